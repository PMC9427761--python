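"""Second- and higher-order texture features: GLCM, GLRLM and NGTDM.

All three matrices are computed in 3D.  Co-occurrence and run-length
statistics aggregate the 13 unique 3D unit directions into one merged matrix
before normalization (merged aggregation — a single deterministic value per
feature); the neighbourhood gray-tone difference matrix uses the full
26-connected neighbourhood restricted to in-ROI voxels.

Inputs are integer level grids from :func:`ringomics.features.discretize`
(levels 1..n_levels inside the ROI, 0 outside).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..errors import DegenerateROIError

# The 13 unique 3D unit offsets (one per +/- direction pair).
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

# Catalogue set: 24 features.  `dissimilarity` is also computed by
# glcm_features but excluded here because on a symmetric merged matrix it
# coincides with difference_average.
GLCM_NAMES: tuple[str, ...] = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
)

GLRLM_NAMES: tuple[str, ...] = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "gray_level_variance",
    "run_length_variance",
    "run_entropy",
)

NGTDM_NAMES: tuple[str, ...] = (
    "coarseness",
    "contrast",
    "busyness",
    "complexity",
    "strength",
)

_COARSENESS_CAP = 1.0e6
_EPS = np.finfo(np.float64).tiny


def _check_roi(roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, dtype=bool)
    if roi.sum() < 2:
        raise DegenerateROIError("texture features need >= 2 in-ROI voxels")
    return roi


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix(levels: np.ndarray, roi: np.ndarray, n_levels: int) -> np.ndarray:
    """Merged symmetric co-occurrence matrix over the 13 unit offsets.

    Returns raw pair counts (each unordered in-ROI pair contributes to both
    (i, j) and (j, i)), shape ``(n_levels, n_levels)``.
    """
    roi = _check_roi(roi)
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    lv = np.asarray(levels, dtype=np.int64)
    for dx, dy, dz in OFFSETS_13:
        src = [slice(max(-d, 0), lv.shape[k] - max(d, 0)) for k, d in enumerate((dx, dy, dz))]
        dst = [slice(max(d, 0), lv.shape[k] + min(d, 0)) for k, d in enumerate((dx, dy, dz))]
        a_roi = roi[tuple(src)]
        b_roi = roi[tuple(dst)]
        both = a_roi & b_roi
        if not both.any():
            continue
        a = lv[tuple(src)][both] - 1
        b = lv[tuple(dst)][both] - 1
        flat = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
        counts += flat.reshape(n_levels, n_levels)
    counts = counts + counts.T
    return counts


def glcm_features(levels: np.ndarray, roi: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 24 (+1) IBSI GLCM features from the merged symmetric matrix.

    Degenerate conventions: when either marginal variance vanishes the
    correlation is 0; information-correlation features are 0 when the
    relevant entropies vanish.
    """
    counts = glcm_matrix(levels, roi, n_levels)
    total = counts.sum()
    if total == 0:
        raise DegenerateROIError("no in-ROI voxel pairs for GLCM")
    p = counts / total
    n = n_levels
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())

    diff = np.abs(ii - jj).astype(np.int64)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel(), minlength=n)[:n]
    k_diff = np.arange(n, dtype=np.float64)
    da = float((k_diff * p_diff).sum())
    dvar = float(((k_diff - da) ** 2 * p_diff).sum())
    nzd = p_diff[p_diff > 0]
    dent = float(-(nzd * np.log2(nzd)).sum())

    summ = (ii + jj).astype(np.int64)
    p_sum = np.bincount(summ.ravel(), weights=p.ravel(), minlength=2 * n + 1)[2:]
    k_sum = np.arange(2, 2 * n + 1, dtype=np.float64)
    sa = float((k_sum * p_sum).sum())
    svar = float(((k_sum - sa) ** 2 * p_sum).sum())
    nzs = p_sum[p_sum > 0]
    sent = float(-(nzs * np.log2(nzs)).sum())

    nz = p[p > 0]
    hxy = float(-(nz * np.log2(nz)).sum())
    pxg = px[px > 0]
    hx = float(-(pxg * np.log2(pxg)).sum())
    pxpy = np.outer(px, px)
    mask = p > 0
    hxy1 = float(-(p[mask] * np.log2(pxpy[mask] + _EPS)).sum())
    mask2 = pxpy > 0
    hxy2 = float(-(pxpy[mask2] * np.log2(pxpy[mask2])).sum())
    ic1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 > 0 else 0.0

    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())
    corr = float(((ii - mu) * (jj - mu) * p).sum() / var) if var > 0 else 0.0

    return {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": dvar,
        "difference_entropy": dent,
        "sum_average": sa,
        "sum_variance": svar,
        "sum_entropy": sent,
        "angular_second_moment": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_normalized": float((p / (1.0 + np.abs(ii - jj) / n)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference_moment_normalized": float(
            (p / (1.0 + (ii - jj) ** 2 / n**2)).sum()
        ),
        "inverse_variance": inv_var,
        "correlation": corr,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "information_correlation_1": ic1,
        "information_correlation_2": ic2,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _runs_along(coords: np.ndarray, lv: np.ndarray, offset: tuple[int, int, int]):
    """Run levels and lengths for one direction, given in-ROI voxel coords.

    Voxels are grouped into lines via the cross product with the direction
    (constant along a line) and ordered by the projection onto the direction;
    consecutive positions differ by |d|^2.
    """
    d = np.asarray(offset, dtype=np.int64)
    t = coords @ d
    cross = np.stack(
        [
            coords[:, 0] * d[1] - coords[:, 1] * d[0],
            coords[:, 0] * d[2] - coords[:, 2] * d[0],
            coords[:, 1] * d[2] - coords[:, 2] * d[1],
        ],
        axis=1,
    )
    order = np.lexsort((t, cross[:, 2], cross[:, 1], cross[:, 0]))
    ts = t[order]
    cs = cross[order]
    ls = lv[order]
    step = int(d @ d)
    same_line = np.all(cs[1:] == cs[:-1], axis=1)
    contiguous = same_line & (ts[1:] - ts[:-1] == step) & (ls[1:] == ls[:-1])
    new_run = np.empty(len(ls), dtype=bool)
    new_run[0] = True
    new_run[1:] = ~contiguous
    run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    levels_of_runs = ls[new_run]
    return levels_of_runs, lengths


def glrlm_matrix(levels: np.ndarray, roi: np.ndarray, n_levels: int) -> np.ndarray:
    """Merged run-length matrix (13 directions summed), shape (n_levels, Lmax)."""
    roi = _check_roi(roi)
    coords = np.argwhere(roi).astype(np.int64)
    lv = np.asarray(levels, dtype=np.int64)[roi]
    max_len = int(max(levels.shape))
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    for off in OFFSETS_13:
        rl, rlen = _runs_along(coords, lv, off)
        np.add.at(mat, (rl - 1, rlen - 1), 1.0)
    return mat


def glrlm_features(levels: np.ndarray, roi: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 16 IBSI GLRLM features from the merged run-length matrix.

    Run percentage uses the merged convention: total runs divided by
    (in-ROI voxel count x 13 directions).
    """
    roi = _check_roi(roi)
    mat = glrlm_matrix(levels, roi, n_levels)
    ns = mat.sum()
    if ns == 0:
        raise DegenerateROIError("no runs for GLRLM")
    nv = float(roi.sum()) * len(OFFSETS_13)
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    ri = mat.sum(axis=1)
    rl = mat.sum(axis=0)
    p = mat / ns
    mu_i = float((i * ri / ns).sum())
    mu_l = float((l * rl / ns).sum())
    nzp = p[p > 0]
    return {
        "short_run_emphasis": float((rl / l**2).sum() / ns),
        "long_run_emphasis": float((rl * l**2).sum() / ns),
        "gray_level_nonuniformity": float((ri**2).sum() / ns),
        "gray_level_nonuniformity_normalized": float((ri**2).sum() / ns**2),
        "run_length_nonuniformity": float((rl**2).sum() / ns),
        "run_length_nonuniformity_normalized": float((rl**2).sum() / ns**2),
        "run_percentage": float(ns / nv),
        "low_gray_level_run_emphasis": float((ri / i**2).sum() / ns),
        "high_gray_level_run_emphasis": float((ri * i**2).sum() / ns),
        "short_run_low_gray_level_emphasis": float(
            (mat / np.outer(i**2, l**2)).sum() / ns
        ),
        "short_run_high_gray_level_emphasis": float(
            (mat * np.outer(i**2, 1.0 / l**2)).sum() / ns
        ),
        "long_run_low_gray_level_emphasis": float(
            (mat * np.outer(1.0 / i**2, l**2)).sum() / ns
        ),
        "long_run_high_gray_level_emphasis": float(
            (mat * np.outer(i**2, l**2)).sum() / ns
        ),
        "gray_level_variance": float(((i - mu_i) ** 2 * ri / ns).sum()),
        "run_length_variance": float(((l - mu_l) ** 2 * rl / ns).sum()),
        "run_entropy": float(-(nzp * np.log2(nzp)).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

_KERNEL_26 = np.ones((3, 3, 3))
_KERNEL_26[1, 1, 1] = 0.0


def ngtdm_table(levels: np.ndarray, roi: np.ndarray, n_levels: int):
    """Per-level occurrence counts n_i and summed deviations s_i.

    For each ROI voxel with at least one 26-connected in-ROI neighbour,
    the absolute difference between its level and the mean level of those
    neighbours accumulates into s at its own level.  Returns
    ``(n, s, n_valid)``.
    """
    roi = _check_roi(roi)
    lv = np.asarray(levels, dtype=np.float64) * roi
    nbr_sum = ndimage.correlate(lv, _KERNEL_26, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(roi.astype(np.float64), _KERNEL_26, mode="constant", cval=0.0)
    valid = roi & (nbr_cnt > 0.5)
    n_valid = int(valid.sum())
    n = np.zeros(n_levels, dtype=np.float64)
    s = np.zeros(n_levels, dtype=np.float64)
    if n_valid == 0:
        return n, s, 0
    lv_v = np.asarray(levels)[valid].astype(np.int64)
    dev = np.abs(np.asarray(levels, dtype=np.float64)[valid] - nbr_sum[valid] / nbr_cnt[valid])
    n += np.bincount(lv_v - 1, minlength=n_levels)[:n_levels]
    s += np.bincount(lv_v - 1, weights=dev, minlength=n_levels)[:n_levels]
    return n, s, n_valid


def ngtdm_features(levels: np.ndarray, roi: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 5 IBSI NGTDM features: coarseness, contrast, busyness, complexity, strength.

    Degenerate conventions: a flat ROI has contrast, busyness, complexity and
    strength 0; coarseness is capped at 1e6 when the deviation sum vanishes.
    """
    n, s, n_valid = ngtdm_table(levels, roi, n_levels)
    if n_valid == 0:
        raise DegenerateROIError("no voxels with in-ROI neighbours for NGTDM")
    p = n / n_valid
    present = p > 0
    n_gp = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    if n_gp > 1:
        pi = p[present]
        ii = i[present]
        diff2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * diff2).sum()
            / (n_gp * (n_gp - 1))
            * (s.sum() / n_valid)
        )
        denom_b = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        busyness = ps / denom_b if denom_b > 0 else 0.0
        si = s[present]
        complexity = float(
            (
                np.abs(ii[:, None] - ii[None, :])
                * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                / (pi[:, None] + pi[None, :])
            ).sum()
            / n_valid
        )
        ssum = float(s.sum())
        strength = (
            float(((pi[:, None] + pi[None, :]) * diff2).sum()) / ssum if ssum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
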