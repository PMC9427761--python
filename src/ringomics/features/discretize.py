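"""Fixed-bin-count intensity discretization inside an ROI."""

from __future__ import annotations

import numpy as np

from ..errors import DegenerateROIError, ValidationError


def discretize(voxels: np.ndarray, roi: np.ndarray, n_bins: int) -> np.ndarray:
    """Map ROI intensities to integer levels 1..n_bins over [min, max].

    Fixed-bin-count discretization: the ROI intensity range is split into
    ``n_bins`` equal-width bins; the maximum lands in the top bin.  A
    constant ROI maps to level 1 everywhere.  Voxels outside the ROI get
    level 0.

    Parameters
    ----------
    voxels : ndarray
        Intensity grid.
    roi : bool ndarray
        Region of interest, same shape.
    n_bins : int
        Number of gray levels, >= 2.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise DegenerateROIError("ROI is empty")
    vals = voxels[roi]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(voxels.shape, dtype=np.int32)
    if hi == lo:
        levels[roi] = 1
        return levels
    lv = np.floor((voxels[roi] - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    np.clip(lv, 1, n_bins, out=lv)
    levels[roi] = lv
    return levels
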