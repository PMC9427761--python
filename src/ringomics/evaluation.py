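"""Evaluation of the radiomics score: ROC/AUC with DeLong confidence
intervals, Kaplan–Meier and log-rank survival comparison, univariate and
multivariate Cox proportional-hazards regression, Harrell's C-index, the
nomogram linear predictor / point scale, and treatment-response rate tables.

Kaplan–Meier and Cox fits delegate to lifelines (Efron tie handling); the
AUC, DeLong variance, C-index and nomogram scaling are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ConvergenceError, ValidationError

__all__ = [
    "RocSummary",
    "CoxSummary",
    "roc_auc",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "c_index",
    "nomogram_score",
    "response_table",
]


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong CI
# ---------------------------------------------------------------------------


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError("AUC must be in [0, 1]")


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels, alpha: float = 0.05) -> RocSummary:
    """AUC as the Mann–Whitney probability (ties count 0.5) with a DeLong
    confidence interval and the empirical operating curve.

    ``labels`` are binary with 1 = positive class.  Raises
    :class:`ValidationError` if only one class is present.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValidationError("both classes must be present for ROC analysis")

    # DeLong structural components via midranks
    allr = _midranks(np.concatenate([pos, neg]))
    rpos = _midranks(pos)
    rneg = _midranks(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (allr[:m] - rpos) / n  # per-positive placement values
    v01 = 1.0 - (allr[m:] - rneg) / m  # per-negative placement values
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n if m > 1 and n > 1 else 0.0
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)

    # operating curve over unique thresholds (descending)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    keep = np.r_[np.diff(s[order]) != 0, True]
    tpr = np.r_[0.0, tps[keep] / m]
    fpr = np.r_[0.0, fps[keep] / n]
    return RocSummary(float(auc), float(lo), float(hi), fpr, tpr)


# ---------------------------------------------------------------------------
# Survival: KM, log-rank, Cox
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator with Greenwood 95% confidence band."""
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events).astype(int)
    if len(t) == 0:
        raise ValidationError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    return SurvivalCurve(
        times=surv.index.to_numpy(np.float64),
        survival=surv.to_numpy(np.float64),
        ci_low=ci.iloc[:, 0].to_numpy(np.float64),
        ci_high=ci.iloc[:, 1].to_numpy(np.float64),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """K-group log-rank chi-square (K-1 df) and its p-value."""
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events).astype(int)
    g = np.asarray(groups)
    if e.sum() < 1:
        raise ValidationError("log-rank needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxSummary:
    """Per-covariate hazard ratios with Wald CIs/p and the model C-index."""

    table: pd.DataFrame  # index = covariates; columns hr, ci_low, ci_high, coef, se, p
    c_index: float
    c_index_ci: tuple[float, float]
    log_likelihood: float
    covariates: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str,
    event_col: str,
    c_index_bootstrap: int = 0,
    seed: int = 0,
) -> CoxSummary:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    Raises :class:`ConvergenceError` with the lifelines diagnostic when the
    partial-likelihood maximization fails, and :class:`ValidationError` for
    event-free data.
    """
    if data[event_col].sum() < 1:
        raise ValidationError("Cox regression needs at least one event")
    df = data[covariates + [time_col, event_col]].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as err:  # lifelines raises ConvergenceError/ValueError
        raise ConvergenceError(f"Cox fit failed: {err}") from err
    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "se": summ["se(coef)"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    lp = cph.predict_partial_hazard(df).to_numpy()
    ci, ci_ci = c_index(
        np.log(lp), df[time_col].to_numpy(), df[event_col].to_numpy(),
        n_bootstrap=c_index_bootstrap, seed=seed,
    )
    return CoxSummary(
        table=table,
        c_index=ci,
        c_index_ci=ci_ci,
        log_likelihood=float(cph.log_likelihood_),
        covariates=list(covariates),
    )


def univariate_cox_screen(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str,
    event_col: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Univariate Cox fit per covariate; returns the table and the
    covariates passing p < alpha (the multivariate entry rule)."""
    rows = []
    for cov in covariates:
        try:
            res = cox_fit(data, [cov], time_col, event_col)
            rows.append(res.table.loc[cov])
        except (ConvergenceError, ValidationError):
            rows.append(
                pd.Series(
                    {"coef": np.nan, "se": np.nan, "hr": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "p": np.nan},
                    name=cov,
                )
            )
    table = pd.DataFrame(rows)
    table.index = covariates
    passing = [c for c in covariates if np.isfinite(table.loc[c, "p"]) and table.loc[c, "p"] < alpha]
    return table, passing


# ---------------------------------------------------------------------------
# Harrell's C-index
# ---------------------------------------------------------------------------


def _c_index_point(lp: np.ndarray, t: np.ndarray, e: np.ndarray) -> tuple[float, int]:
    """Concordant fraction over usable pairs (ties in predictor count 0.5)."""
    # A pair (i, j) is usable when the earlier time is an event.
    conc = 0.0
    usable = 0
    ev = np.flatnonzero(e == 1)
    for i in ev:
        later = (t > t[i]) | ((t == t[i]) & (e == 0))
        usable += int(later.sum())
        conc += np.sum(lp[i] > lp[later]) + 0.5 * np.sum(lp[i] == lp[later])
    if usable == 0:
        raise ValidationError("no usable pairs for the C-index")
    return conc / usable, usable


def c_index(
    linear_predictor,
    times,
    events,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Harrell's concordance index with a seeded bootstrap CI.

    Higher predictor = higher risk (shorter time) counts as concordant.
    Set ``n_bootstrap=0`` to skip the CI (returned as (nan, nan)).
    """
    lp = np.asarray(linear_predictor, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events).astype(int)
    point, _ = _c_index_point(lp, t, e)
    if n_bootstrap <= 0:
        return float(point), (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    n = len(t)
    draws = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            ci_b, _ = _c_index_point(lp[idx], t[idx], e[idx])
            draws.append(ci_b)
        except ValidationError:
            continue
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return float(point), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Nomogram linear predictor and points
# ---------------------------------------------------------------------------


def nomogram_score(
    cox: CoxSummary,
    record,
    covariate_ranges: dict[str, tuple[float, float]],
) -> tuple[float, float]:
    """(total points, linear predictor) of one record under a Cox model.

    Each covariate contributes ``coef * (x - ref)`` to the linear predictor,
    with the reference at the low end of its stated range; points scale that
    contribution so the single largest covariate effect span equals 100.
    Total points are monotone in the linear predictor.
    """
    spans = {}
    for cov in cox.covariates:
        lo, hi = covariate_ranges[cov]
        spans[cov] = abs(cox.coef(cov)) * (hi - lo)
    max_span = max(spans.values())
    if max_span <= 0:
        raise ValidationError("all covariate effects are zero; no point scale")
    lp = 0.0
    points = 0.0
    for cov in cox.covariates:
        try:
            x = float(record[cov])
        except (KeyError, IndexError) as err:
            raise ValidationError(f"record is missing covariate {cov!r}") from err
        lo, hi = covariate_ranges[cov]
        beta = cox.coef(cov)
        lp += beta * (x - lo)
        # per-covariate points grow along the direction of increasing hazard
        contrib = beta * (x - lo) if beta >= 0 else beta * (x - hi)
        points += abs(contrib) / max_span * 100.0
    return float(points), float(lp)


# ---------------------------------------------------------------------------
# Treatment response tables
# ---------------------------------------------------------------------------


def response_table(
    responses: pd.Series,
    rs_groups: pd.Series,
    rs: pd.Series | None = None,
) -> dict:
    """Response-rate table per RS group plus group comparisons.

    Rates: objective response (CR+PR), disease control (CR+PR+SD) and PD per
    RS group, as percentages; empty groups report NaN, never 0.  The chi²
    test runs on the group x category contingency table, and when ``rs`` is
    given, pairwise two-tailed unpaired t-tests compare the RS across
    response groups (OR vs SD vs PD).
    """
    if responses.isna().any():
        raise ValidationError("every record needs a response category")
    cats = {"CR", "PR", "SD", "PD"}
    bad = set(responses.unique()) - cats
    if bad:
        raise ValidationError(f"unknown response categories {sorted(bad)}")
    groups = sorted(rs_groups.unique())
    rates = {}
    for g in groups:
        sel = responses[rs_groups == g]
        n = len(sel)
        if n == 0:
            rates[g] = {"n": 0, "or_rate": np.nan, "dcr_rate": np.nan, "pd_rate": np.nan}
            continue
        orr = sel.isin(["CR", "PR"]).mean() * 100.0
        dcr = sel.isin(["CR", "PR", "SD"]).mean() * 100.0
        pdr = (sel == "PD").mean() * 100.0
        rates[g] = {"n": n, "or_rate": float(orr), "dcr_rate": float(dcr), "pd_rate": float(pdr)}

    contingency = pd.crosstab(rs_groups, responses)
    chi2_p = np.nan
    if contingency.shape[0] > 1 and contingency.shape[1] > 1:
        chi2_p = float(stats.chi2_contingency(contingency.to_numpy())[1])

    ttests = {}
    if rs is not None:
        coarse = responses.map(lambda r: "OR" if r in ("CR", "PR") else r)
        levels = [l for l in ("OR", "SD", "PD") if (coarse == l).sum() > 1]
        for a_i in range(len(levels)):
            for b_i in range(a_i + 1, len(levels)):
                a, b = levels[a_i], levels[b_i]
                xa = rs[coarse == a]
                xb = rs[coarse == b]
                tt = stats.ttest_ind(xa, xb, equal_var=True)
                ttests[f"{a}_vs_{b}"] = {
                    "t": float(tt.statistic),
                    "p": float(tt.pvalue),
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                }
    return {"rates": rates, "chi2_p": chi2_p, "rs_ttests": ttests}
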