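"""Independent brute-force oracles used by the tests.

Each oracle is a direct, unoptimized transcription of the defining
enumeration and shares no code with the implementation it checks.
"""

import numpy as np

OFFSETS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def brute_ring(tumor: np.ndarray, spacing, inner_mm: float, outer_mm: float) -> np.ndarray:
    """Ring voxels by per-voxel min distance against all boundary voxels.

    Boundary voxels = tumor voxels with a 6-neighbour outside the tumor (or
    at the grid edge).
    """
    sp = np.asarray(spacing, dtype=float)
    shape = tumor.shape
    boundary = []
    for idx in np.argwhere(tumor):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = idx + d
            if np.any(nb < 0) or np.any(nb >= shape) or not tumor[tuple(nb)]:
                boundary.append(idx)
                break
    boundary = np.asarray(boundary, dtype=float)
    ring = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(shape):
        d = np.sqrt((((np.asarray(idx) - boundary) * sp) ** 2).sum(axis=1)).min()
        sd = -d if tumor[idx] else d
        ring[idx] = (-inner_mm < sd <= outer_mm)
    return ring


def brute_glcm(levels: np.ndarray, roi: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    shape = levels.shape
    mat = np.zeros((n_levels, n_levels))
    for idx in np.argwhere(roi):
        for off in OFFSETS_13:
            nb = idx + np.asarray(off)
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            nb = tuple(nb)
            if not roi[nb]:
                continue
            a, b = levels[tuple(idx)], levels[nb]
            mat[a - 1, b - 1] += 1
            mat[b - 1, a - 1] += 1
    return mat


def brute_glrlm(levels: np.ndarray, roi: np.ndarray, n_levels: int) -> np.ndarray:
    """Merged run-length matrix by walking every line in every direction."""
    shape = levels.shape
    max_len = max(shape)
    mat = np.zeros((n_levels, max_len))
    for off in OFFSETS_13:
        d = np.asarray(off)
        visited = np.zeros(shape, dtype=bool)
        for start in np.ndindex(shape):
            prev = np.asarray(start) - d
            if (
                np.all(prev >= 0)
                and np.all(prev < shape)
            ):
                continue  # not a line start for this direction
            pos = np.asarray(start)
            run_level, run_len = None, 0
            while np.all(pos >= 0) and np.all(pos < shape):
                p = tuple(pos)
                assert not visited[p]
                visited[p] = True
                if roi[p]:
                    lv = levels[p]
                    if lv == run_level:
                        run_len += 1
                    else:
                        if run_level is not None:
                            mat[run_level - 1, run_len - 1] += 1
                        run_level, run_len = lv, 1
                else:
                    if run_level is not None:
                        mat[run_level - 1, run_len - 1] += 1
                    run_level, run_len = None, 0
                pos = pos + d
            if run_level is not None:
                mat[run_level - 1, run_len - 1] += 1
        assert visited.all()
    return mat


def brute_ngtdm(levels: np.ndarray, roi: np.ndarray, n_levels: int):
    """Per-level (n_i, s_i) by explicit 26-neighbourhood loops."""
    shape = levels.shape
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    n_valid = 0
    for idx in np.argwhere(roi):
        nbrs = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    nb = idx + (dx, dy, dz)
                    if np.all(nb >= 0) and np.all(nb < shape) and roi[tuple(nb)]:
                        nbrs.append(levels[tuple(nb)])
        if not nbrs:
            continue
        n_valid += 1
        lv = levels[tuple(idx)]
        n[lv - 1] += 1
        s[lv - 1] += abs(lv - float(np.mean(nbrs)))
    return n, s, n_valid


def brute_auc(scores, labels) -> float:
    """Concordant-pair fraction with 0.5 for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_c_index(lp, times, events) -> float:
    """Pair enumeration: usable pairs have the earlier time as an event."""
    lp = np.asarray(lp, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    conc, usable = 0.0, 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if e[i] == 1 and (t[i] < t[j] or (t[i] == t[j] and e[j] == 0)):
                usable += 1
                if lp[i] > lp[j]:
                    conc += 1.0
                elif lp[i] == lp[j]:
                    conc += 0.5
    return conc / usable


def cox_partial_loglik(beta: float, x, times, events) -> float:
    """Breslow partial log-likelihood for a single covariate (distinct times)."""
    x = np.asarray(x, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    ll = 0.0
    for i in np.flatnonzero(e == 1):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def brute_cox_coef(x, times, events, lo=-5.0, hi=5.0, tol=1e-6) -> float:
    """Golden-section maximization of the partial likelihood on a grid."""
    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    while b - a > tol:
        if cox_partial_loglik(c, x, times, events) > cox_partial_loglik(d, x, times, events):
            b = d
        else:
            a = c
        c, d = b - gr * (b - a), a + gr * (b - a)
    return (a + b) / 2


def semivariogram_range(field: np.ndarray, roi: np.ndarray, max_lag: int = 8) -> float:
    """First axis-lag (voxels) where the empirical semivariance reaches 90%
    of its max-lag value; larger = longer spatial correlation."""
    gammas = []
    for lag in range(1, max_lag + 1):
        diffs = []
        for axis in range(3):
            a = [slice(None)] * 3
            b = [slice(None)] * 3
            a[axis] = slice(None, -lag)
            b[axis] = slice(lag, None)
            both = roi[tuple(a)] & roi[tuple(b)]
            if both.any():
                diffs.append(((field[tuple(a)][both] - field[tuple(b)][both]) ** 2))
        gammas.append(0.5 * np.mean(np.concatenate(diffs)))
    gammas = np.asarray(gammas)
    sill = gammas[-1]
    reach = np.flatnonzero(gammas >= 0.9 * sill)
    return float(reach[0] + 1) if len(reach) else float(max_lag)
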