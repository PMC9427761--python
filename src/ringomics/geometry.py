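"""Image volumes, binary masks, NIfTI I/O, resampling and peritumoral ring ROIs.

The geometry substrate for the whole pipeline: a CT-like scalar grid in
Hounsfield units with millimetre spacing, paired binary masks on the same
grid, and the ring-shaped peritumoral region of interest built from a signed
Euclidean distance to the tumor boundary.

Conventions
-----------
* World coordinates are millimetres; voxel indices are 0-based (x, y, z).
* The tumor *boundary* is the set of tumor voxels with at least one
  6-connected background neighbour.  The signed distance of a voxel is the
  Euclidean distance (in mm, spacing-aware) from its centre to the nearest
  boundary-voxel centre, negative for voxels inside the tumor.  Boundary
  voxels themselves have distance 0.
* The peritumoral ring spans signed distances in ``(-inner_mm, +outer_mm]``
  (default 1 mm inside to 2 mm outside, a 3 mm thick shell), minus any
  exclusion mask.  The intratumoral ROI remains the full tumor mask; the
  1 mm overlap between ring and tumor is intentional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import AlignmentError, DegenerateROIError, ValidationError

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "RoiSet",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "signed_distance_mm",
    "build_peritumoral_ring",
    "exclusion_from_hu",
]


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValidationError(f"expected a length-3 triple, got {x!r}")
    return t


@dataclass
class ImageVolume:
    """A 3D scalar grid in Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in HU; must be finite.
    spacing_mm : triple of float
        Voxel edge lengths along (x, y, z); strictly positive.
    origin_mm : triple of float
        World position of the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValidationError("volume must be 3D")
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "ImageVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class BinaryMask:
    """A boolean grid sharing its geometry with a paired :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValidationError("mask must be 3D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError(
                    f"mask must be binary; found values {uniq[:10].tolist()}"
                )
            arr = arr.astype(bool)
        self.voxels = arr
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def count(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other: "ImageVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class RoiSet:
    """Tumor mask, peritumoral ring mask and the exclusion mask that carved it.

    Invariants: all three masks share one grid and the ring never intersects
    the exclusion mask.
    """

    tumor_mask: BinaryMask
    ring_mask: BinaryMask
    exclusion_mask: BinaryMask

    def __post_init__(self) -> None:
        if not (
            self.tumor_mask.same_grid(self.ring_mask)
            and self.tumor_mask.same_grid(self.exclusion_mask)
        ):
            raise AlignmentError("RoiSet masks must share one grid")
        if np.any(self.ring_mask.voxels & self.exclusion_mask.voxels):
            raise ValidationError("ring mask intersects exclusion mask")

    regions: dict = field(default_factory=dict, init=False, repr=False)

    def region_mask(self, region: str) -> BinaryMask:
        if region == "intratumoral":
            return self.tumor_mask
        if region == "peritumoral":
            return self.ring_mask
        raise ValidationError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# NIfTI I/O.  The affine is diag(spacing) with the origin in its last column;
# only axis-aligned affines are produced, and reading tolerates any affine
# whose rotational part is diagonal up to sign.
# ---------------------------------------------------------------------------


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        volume.voxels.astype(np.float32), _affine(volume.spacing_mm, volume.origin_mm)
    )
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm)
    )
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume, preserving spacing and origin."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asanyarray(img.dataobj, dtype=np.float64), spacing, origin)


def read_mask(path: str | Path, reference: ImageVolume) -> BinaryMask:
    """Read a NIfTI binary mask and validate it against a reference grid.

    Raises
    ------
    AlignmentError
        If shape, spacing or origin differ from the reference volume.
    ValidationError
        If the file contains values other than 0/1.
    """
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    mask = BinaryMask(np.asanyarray(img.dataobj), spacing, origin)
    if not mask.same_grid(reference):
        raise AlignmentError(
            f"mask grid {mask.shape}/{mask.spacing_mm} does not match "
            f"volume grid {reference.shape}/{reference.spacing_mm}"
        )
    return mask


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_isotropic(
    volume: ImageVolume, mask: BinaryMask, target_mm: float
) -> tuple[ImageVolume, BinaryMask]:
    """Resample a volume (trilinear) and mask (nearest) to isotropic spacing.

    Returns the inputs untouched when the grid is already isotropic at the
    target.  Raises :class:`DegenerateROIError` if the mask empties.
    """
    if target_mm <= 0:
        raise ValidationError("target_mm must be positive")
    if not volume.same_grid(mask):
        raise AlignmentError("volume and mask must share a grid before resampling")
    if np.allclose(volume.spacing_mm, (target_mm,) * 3):
        return volume, mask
    zoom = np.asarray(volume.spacing_mm) / target_mm
    vox = ndimage.zoom(volume.voxels, zoom, order=1, mode="nearest")
    mvox = ndimage.zoom(mask.voxels.astype(np.uint8), zoom, order=0, mode="nearest")
    out_v = ImageVolume(vox, (target_mm,) * 3, volume.origin_mm)
    out_m = BinaryMask(mvox.astype(bool), (target_mm,) * 3, mask.origin_mm)
    if out_m.count() == 0 and mask.count() > 0:
        raise DegenerateROIError("mask became empty after resampling")
    return out_v, out_m


# ---------------------------------------------------------------------------
# Signed distance and ring construction
# ---------------------------------------------------------------------------


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Tumor voxels with a 6-connected background neighbour (grid edge counts)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def signed_distance_mm(tumor: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance (mm) to the tumor boundary-voxel set.

    Positive outside the tumor, negative inside, zero on boundary voxels.
    """
    if tumor.count() == 0:
        raise DegenerateROIError("tumor mask is empty")
    bnd = boundary_voxels(tumor.voxels)
    dist = ndimage.distance_transform_edt(~bnd, sampling=tumor.spacing_mm)
    sd = np.where(tumor.voxels, -dist, dist)
    return sd


def build_peritumoral_ring(
    tumor: BinaryMask,
    outer_mm: float = 2.0,
    inner_mm: float = 1.0,
    exclusion: BinaryMask | None = None,
) -> RoiSet:
    """Build the ring ROI spanning ``inner_mm`` inside to ``outer_mm`` outside.

    The ring is the signed-distance band ``(-inner_mm, +outer_mm]`` minus the
    exclusion mask.  With the defaults (2 mm dilation, 1 mm erosion) the shell
    is 3 mm thick.  The intratumoral ROI stays the full tumor mask.

    Raises
    ------
    DegenerateROIError
        If the tumor is empty or the ring empties after exclusion.
    ValidationError
        On negative band widths or a zero-width band.
    """
    if outer_mm < 0 or inner_mm < 0 or (outer_mm == 0 and inner_mm == 0):
        raise ValidationError("band widths must be >= 0 and not both 0")
    if exclusion is not None and not tumor.same_grid(exclusion):
        raise AlignmentError("exclusion mask grid differs from tumor grid")
    sd = signed_distance_mm(tumor)
    ring = (sd > -inner_mm) & (sd <= outer_mm)
    if exclusion is None:
        exclusion = BinaryMask(
            np.zeros(tumor.shape, dtype=bool), tumor.spacing_mm, tumor.origin_mm
        )
    ring &= ~exclusion.voxels
    if not ring.any():
        raise DegenerateROIError("peritumoral ring is empty after exclusion")
    ring_mask = BinaryMask(ring, tumor.spacing_mm, tumor.origin_mm)
    return RoiSet(tumor_mask=tumor, ring_mask=ring_mask, exclusion_mask=exclusion)


def exclusion_from_hu(
    volume: ImageVolume, air_hu: float = -500.0, vessel_hu: float = 300.0
) -> BinaryMask:
    """Flag voxels outside the soft-tissue HU window as excluded.

    Air cavities fall below ``air_hu``; contrast-filled vessels and bone rise
    above ``vessel_hu``.  Purely intensity-based: anatomical adjacency is not
    modelled.
    """
    if not np.isfinite(air_hu) or not np.isfinite(vessel_hu) or air_hu >= vessel_hu:
        raise ValidationError("need finite thresholds with air_hu < vessel_hu")
    excl = (volume.voxels < air_hu) | (volume.voxels > vessel_hu)
    return BinaryMask(excl, volume.spacing_mm, volume.origin_mm)
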