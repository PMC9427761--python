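"""Radiomics signature construction: mRMR pre-selection, LASSO logistic
regression with 5-fold cross-validation, the radiomics score (RS) and its
tertile grouping.

The training label contrasts NLR-High (1) against NLR-Low (0); Mix cases do
not enter the fit.  The RS of a case is the logistic linear predictor
``intercept + sum(coef * z-scored feature)`` and the three RS groups are cut
at the empirical tertiles of the training RS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .errors import SchemaError, SignatureEmptyError, ValidationError

__all__ = [
    "nlr_status",
    "mrmr_rank",
    "lasso_logistic_cv",
    "compute_rs",
    "assign_rs_group",
    "fit_signature",
    "RadiomicsSignature",
]

RS_GROUPS = ("RS-Low", "RS-Middle", "RS-High")


def nlr_status(nlr_intra: float, nlr_peri: float) -> str:
    """High / Mix / Low by the threshold-1 rule (boundary 1.0 counts as high).

    High: both ratios >= 1; Low: both < 1; Mix: exactly one >= 1.
    """
    for v in (nlr_intra, nlr_peri):
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"NLR must be a finite non-negative ratio, got {v!r}")
    hi_i, hi_p = nlr_intra >= 1.0, nlr_peri >= 1.0
    if hi_i and hi_p:
        return "High"
    if not hi_i and not hi_p:
        return "Low"
    return "Mix"


# ---------------------------------------------------------------------------
# mRMR (FCD variant: F-statistic relevance minus mean |Pearson| redundancy)
# ---------------------------------------------------------------------------


def mrmr_rank(features: pd.DataFrame, labels: np.ndarray, k: int) -> list[str]:
    """Greedy maximum-relevance minimum-redundancy feature ranking.

    Relevance of a feature is its one-way ANOVA F-statistic against the
    binary label; redundancy is the mean absolute Pearson correlation with
    the already-selected set; each step picks the feature maximizing
    relevance - redundancy (the FCD difference criterion).  Deterministic:
    ties break in catalogue (column) order.  Constant columns get zero
    relevance and zero redundancy.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    if k > features.shape[1]:
        raise ValidationError("k exceeds the number of features")
    X = features.to_numpy(dtype=np.float64)
    names = list(features.columns)
    n, m = X.shape
    sd = X.std(axis=0)
    ok = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are handled below
        fstat, _ = f_classif(X, y)
    fstat = np.where(np.isfinite(fstat) & ok, fstat, 0.0)
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]

    selected: list[int] = []
    red_sum = np.zeros(m)
    remaining = np.ones(m, dtype=bool)
    for _ in range(k):
        if selected:
            score = fstat - red_sum / len(selected)
        else:
            score = fstat.copy()
        score[~remaining] = -np.inf
        j = int(np.argmax(score))  # argmax takes the first max -> column-order ties
        selected.append(j)
        remaining[j] = False
        r = np.abs(Z.T @ Z[:, j]) / n  # |Pearson| of every feature with feature j
        red_sum += np.where(ok, r, 0.0)
    return [names[j] for j in selected]


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------


@dataclass
class RadiomicsSignature:
    """Fitted LASSO-logistic signature.

    ``coefficients`` apply to z-scored features; the RS of a row is
    ``intercept + sum_j coef_j * (x_j - mean_j) / sd_j`` over the selected
    features.
    """

    selected: list[str]
    coefficients: dict[str, float]
    intercept: float
    standardization: dict[str, tuple[float, float]]  # name -> (mean, sd)
    lambda_: float
    tertile_cutoffs: tuple[float, float]
    group_labels: tuple[str, ...] = RS_GROUPS
    mrmr_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.selected) < 1:
            raise SignatureEmptyError("signature must keep at least one feature")
        q1, q2 = self.tertile_cutoffs
        if q1 > q2:
            raise ValidationError("tertile cutoffs must satisfy q1 <= q2")
        for name in self.selected:
            if not np.isfinite(self.coefficients[name]):
                raise ValidationError(f"non-finite coefficient for {name}")
            if self.standardization[name][1] <= 0:
                raise ValidationError(f"non-positive standardization SD for {name}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected": self.selected,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "lambda": self.lambda_,
            "tertile_cutoffs": list(self.tertile_cutoffs),
            "group_labels": list(self.group_labels),
            "mrmr_features": self.mrmr_features,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RadiomicsSignature":
        d = json.loads(Path(path).read_text())
        return cls(
            selected=d["selected"],
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            standardization={k: (float(v[0]), float(v[1])) for k, v in d["standardization"].items()},
            lambda_=float(d["lambda"]),
            tertile_cutoffs=(float(d["tertile_cutoffs"][0]), float(d["tertile_cutoffs"][1])),
            group_labels=tuple(d["group_labels"]),
            mrmr_features=d.get("mrmr_features", []),
        )


def lasso_logistic_cv(
    features: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> RadiomicsSignature:
    """LASSO logistic regression with stratified K-fold CV penalty choice.

    Features are z-scored with training statistics; the penalty minimizes
    the mean cross-validated binomial deviance over a logarithmic lambda
    grid, and the model is refit at that penalty on the full training data.
    Nonzero-coefficient features form the signature; tertile cutoffs are the
    empirical 1/3 and 2/3 quantiles of the training RS.

    Raises
    ------
    SignatureEmptyError
        If every coefficient is zero at the chosen penalty (e.g. a grid of
        only very large penalties).
    """
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("labels must be binary")
    if counts.min() < folds:
        raise ValidationError(f"need >= {folds} cases per class for {folds}-fold CV")
    X = features.to_numpy(dtype=np.float64)
    names = list(features.columns)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        bad = [n for n, s in zip(names, sd) if s <= 0]
        raise ValidationError(f"constant feature columns cannot be standardized: {bad[:5]}")
    Z = (X - mean) / sd

    if lambda_grid is None:
        lambda_grid = np.logspace(-3, 1.5, 40)
    # sklearn parameterizes by C = 1 / (n * lambda) relative to mean deviance
    Cs = 1.0 / (len(y) * np.asarray(lambda_grid))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        refit=True,
        max_iter=5000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(Z, y)
    coef = model.coef_.ravel()
    chosen_c = float(model.C_[0])
    lam = 1.0 / (len(y) * chosen_c)
    nz = np.flatnonzero(coef != 0.0)
    if len(nz) == 0:
        raise SignatureEmptyError(
            "all LASSO coefficients are zero at the selected penalty "
            f"(lambda={lam:.4g}); inspect/expand the lambda grid"
        )
    selected = [names[j] for j in nz]
    rs_train = float(model.intercept_[0]) + Z @ coef
    q1, q2 = np.quantile(rs_train, [1 / 3, 2 / 3])
    return RadiomicsSignature(
        selected=selected,
        coefficients={names[j]: float(coef[j]) for j in nz},
        intercept=float(model.intercept_[0]),
        standardization={names[j]: (float(mean[j]), float(sd[j])) for j in nz},
        lambda_=lam,
        tertile_cutoffs=(float(q1), float(q2)),
    )


def compute_rs(signature: RadiomicsSignature, feature_row) -> float:
    """RS of one case: intercept + sum of coefficient x standardized value.

    ``feature_row`` is any mapping (dict / pandas Series) containing every
    selected feature; a missing feature raises :class:`SchemaError` — no
    imputation.
    """
    rs = signature.intercept
    for name in signature.selected:
        try:
            x = float(feature_row[name])
        except (KeyError, IndexError) as err:
            raise SchemaError(f"feature row is missing selected feature {name!r}") from err
        mu, sd = signature.standardization[name]
        rs += signature.coefficients[name] * (x - mu) / sd
    return float(rs)


def compute_rs_table(signature: RadiomicsSignature, features: pd.DataFrame) -> pd.Series:
    """Vectorized RS for a feature table (rows = cases)."""
    missing = [n for n in signature.selected if n not in features.columns]
    if missing:
        raise SchemaError(f"feature table is missing selected features {missing[:5]}")
    rs = np.full(len(features), signature.intercept, dtype=np.float64)
    for name in signature.selected:
        mu, sd = signature.standardization[name]
        rs += signature.coefficients[name] * (features[name].to_numpy(np.float64) - mu) / sd
    return pd.Series(rs, index=features.index, name="rs")


def assign_rs_group(rs: float, cutoffs: tuple[float, float]) -> str:
    """Tertile group: RS <= q1 -> RS-Low; q1 < RS <= q2 -> RS-Middle; else RS-High."""
    q1, q2 = cutoffs
    if q1 > q2:
        raise ValidationError("cutoffs must satisfy q1 <= q2")
    if rs <= q1:
        return "RS-Low"
    if rs <= q2:
        return "RS-Middle"
    return "RS-High"


def fit_signature(
    features: pd.DataFrame,
    nlr_status_per_case: pd.Series,
    k: int = 30,
    folds: int = 5,
    seed: int = 0,
) -> RadiomicsSignature:
    """End-to-end training: mRMR (top-k) then LASSO-logistic CV on
    High (1) vs Low (0); Mix cases are excluded from fitting."""
    status = nlr_status_per_case.reindex(features.index)
    keep = status.isin(["High", "Low"])
    if keep.sum() < 2 * folds:
        raise ValidationError("too few High/Low cases to fit the signature")
    X = features.loc[keep]
    y = (status.loc[keep] == "High").to_numpy(int)
    # drop constant columns up front; they carry no signal and break z-scoring
    variable = X.std(axis=0) > 0
    X = X.loc[:, variable]
    ranked = mrmr_rank(X, y, k=min(k, X.shape[1]))
    sig = lasso_logistic_cv(X[ranked], y, folds=folds, seed=seed)
    sig.mrmr_features = ranked
    return sig
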