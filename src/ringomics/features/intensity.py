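"""First-order (histogram) intensity features.

14 features on the ROI intensity multiset.  Entropy and uniformity use a
fixed 64-bin discretization of the ROI range so they are well defined for
continuous HU values.  Conventions for degenerate (constant) ROIs: variance,
skewness and kurtosis are 0, entropy 0, uniformity 1.
"""

from __future__ import annotations

import numpy as np

from ..errors import DegenerateROIError

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "mean_absolute_deviation",
    "root_mean_square",
    "uniformity",
)

_ENTROPY_BINS = 64


def first_order_features(values: np.ndarray) -> dict[str, float]:
    """Compute the 14 first-order features of an intensity multiset.

    ``values`` is the flat array of in-ROI intensities; order does not
    matter.  Raises :class:`DegenerateROIError` for fewer than 2 voxels.
    Variance is the population variance; kurtosis is excess kurtosis
    (0 for a Gaussian).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 2:
        raise DegenerateROIError("first-order features need >= 2 voxels")
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    centred = x - mean
    if sd > 0:
        skew = float(np.mean(centred**3) / sd**3)
        kurt = float(np.mean(centred**4) / sd**4 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        idx = np.floor((x - lo) / (hi - lo) * _ENTROPY_BINS).astype(np.int64)
        np.clip(idx, 0, _ENTROPY_BINS - 1, out=idx)
        p = np.bincount(idx, minlength=_ENTROPY_BINS).astype(np.float64) / x.size
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        uniformity = float((p**2).sum())
    else:
        entropy = 0.0
        uniformity = 1.0
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "minimum": lo,
        "maximum": hi,
        "range": hi - lo,
        "variance": var,
        "standard_deviation": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "mean_absolute_deviation": float(np.abs(centred).mean()),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "uniformity": uniformity,
    }
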