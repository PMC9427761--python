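"""Feature catalogue and per-case extraction.

Per region: 14 first-order + 8 shape + 45 texture features (24 GLCM +
16 GLRLM + 5 NGTDM) at each of 6 bin counts {8, 16, 32, 64, 128, 256} =
270 texture, 292 per region, 584 per case.  Column names follow
``<region-prefix>_<family>_<feature>[_b<bins>]`` with prefixes ``intra`` /
``peri``; order is fixed by the catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DegenerateROIError
from ..geometry import ImageVolume, RoiSet
from .discretize import discretize
from .intensity import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLRLM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    glrlm_features,
    ngtdm_features,
)

DEFAULT_BIN_COUNTS: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
REGIONS: tuple[str, ...] = ("intratumoral", "peritumoral")
_PREFIX = {"intratumoral": "intra", "peritumoral": "peri"}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one catalogue column."""

    name: str  # full column name, e.g. "peri_glcm_contrast_b32"
    region: str  # "intratumoral" | "peritumoral"
    family: str  # "first_order" | "shape" | "glcm" | "glrlm" | "ngtdm"
    feature: str  # base feature name within the family
    bin_count: int | None  # texture families only


def build_catalogue(
    bin_counts: tuple[int, ...] = DEFAULT_BIN_COUNTS,
) -> list[FeatureDescriptor]:
    """The full ordered feature catalogue for both regions."""
    cat: list[FeatureDescriptor] = []
    for region in REGIONS:
        pre = _PREFIX[region]
        for f in FIRST_ORDER_NAMES:
            cat.append(FeatureDescriptor(f"{pre}_firstorder_{f}", region, "first_order", f, None))
        for f in SHAPE_NAMES:
            cat.append(FeatureDescriptor(f"{pre}_shape_{f}", region, "shape", f, None))
        for nb in bin_counts:
            for family, names in (
                ("glcm", GLCM_NAMES),
                ("glrlm", GLRLM_NAMES),
                ("ngtdm", NGTDM_NAMES),
            ):
                for f in names:
                    cat.append(
                        FeatureDescriptor(f"{pre}_{family}_{f}_b{nb}", region, family, f, nb)
                    )
    return cat


def catalogue_names(bin_counts: tuple[int, ...] = DEFAULT_BIN_COUNTS) -> list[str]:
    return [d.name for d in build_catalogue(bin_counts)]


def _check_catalogue_arithmetic() -> None:
    per_region = len(FIRST_ORDER_NAMES) + len(SHAPE_NAMES) + 45 * len(DEFAULT_BIN_COUNTS)
    assert len(FIRST_ORDER_NAMES) == 14
    assert len(SHAPE_NAMES) == 8
    assert len(GLCM_NAMES) + len(GLRLM_NAMES) + len(NGTDM_NAMES) == 45
    assert per_region == 292, per_region
    assert len(build_catalogue()) == 584


_check_catalogue_arithmetic()


def extract_region(
    volume: ImageVolume,
    roi_voxels: np.ndarray,
    region: str,
    bin_counts: tuple[int, ...] = DEFAULT_BIN_COUNTS,
    spacing_mm=None,
    origin_mm=(0.0, 0.0, 0.0),
) -> dict[str, float]:
    """All 292 features of one region; keys are full catalogue names."""
    from ..geometry import BinaryMask

    pre = _PREFIX[region]
    spacing = spacing_mm if spacing_mm is not None else volume.spacing_mm
    if not roi_voxels.any():
        raise DegenerateROIError(f"{region} ROI is empty")
    out: dict[str, float] = {}
    vals = volume.voxels[roi_voxels]
    for k, v in first_order_features(vals).items():
        out[f"{pre}_firstorder_{k}"] = v
    mask = BinaryMask(roi_voxels, spacing, origin_mm)
    for k, v in shape_features(mask).items():
        out[f"{pre}_shape_{k}"] = v
    for nb in bin_counts:
        levels = discretize(volume.voxels, roi_voxels, nb)
        try:
            gl = glcm_features(levels, roi_voxels, nb)
            rl = glrlm_features(levels, roi_voxels, nb)
            ng = ngtdm_features(levels, roi_voxels, nb)
        except DegenerateROIError as err:
            raise DegenerateROIError(f"{region}: {err}") from err
        for k in GLCM_NAMES:
            out[f"{pre}_glcm_{k}_b{nb}"] = gl[k]
        for k in GLRLM_NAMES:
            out[f"{pre}_glrlm_{k}_b{nb}"] = rl[k]
        for k in NGTDM_NAMES:
            out[f"{pre}_ngtdm_{k}_b{nb}"] = ng[k]
    return out


def extract_case(
    volume: ImageVolume,
    rois: RoiSet,
    bin_counts: tuple[int, ...] = DEFAULT_BIN_COUNTS,
) -> dict[str, float]:
    """The full 584-feature row for one case, ordered by the catalogue.

    Raises :class:`DegenerateROIError` naming the region when an ROI is
    empty or too small.
    """
    row: dict[str, float] = {}
    for region in REGIONS:
        mask = rois.region_mask(region)
        row.update(
            extract_region(
                volume,
                mask.voxels,
                region,
                bin_counts,
                spacing_mm=mask.spacing_mm,
                origin_mm=mask.origin_mm,
            )
        )
    names = catalogue_names(bin_counts)
    ordered = {n: row[n] for n in names}
    bad = [n for n, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise DegenerateROIError(f"non-finite features: {bad[:5]}")
    return ordered
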