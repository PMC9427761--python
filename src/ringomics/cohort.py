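"""Seeded synthetic cohorts: CT-like phantoms with tumor masks and linked
clinical records.

Each case carries a latent immune-microenvironment class — the
neutrophil-to-lymphocyte ratio (NLR) status High / Mix / Low, thresholded at
1 in the intratumoral and peritumoral regions — and the image texture inside
and immediately around the tumor is a stationary Gaussian random field whose
correlation length depends on that class.  Survival follows a Weibull
proportional-hazards model with a class-dependent log hazard ratio;
treatment response is a per-class categorical draw over CR/PR/SD/PD.

The generator is a pure function of (config, seed): identical inputs yield
bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .geometry import BinaryMask, ImageVolume, write_mask, write_volume

CLASSES = ("High", "Mix", "Low")
RESPONSES = ("CR", "PR", "SD", "PD")

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass(frozen=True)
class TextureParams:
    """Gaussian-random-field parameters of one region for one class."""

    correlation_length_mm: float
    intensity_sd_hu: float
    mean_hu: float

    def validate(self) -> None:
        if self.correlation_length_mm <= 0:
            raise ValidationError("correlation_length_mm must be > 0")
        if self.intensity_sd_hu < 0:
            raise ValidationError("intensity_sd_hu must be >= 0")


# Default planted effect: the class separates by texture correlation length
# (High 4 mm vs Low 2 mm) at equal SD 15 HU and equal mean, in both regions,
# so the signal is purely textural.
_HIGH = TextureParams(4.0, 15.0, 45.0)
_LOW = TextureParams(2.0, 15.0, 45.0)


def default_texture_params() -> dict[str, dict[str, TextureParams]]:
    return {
        "High": {"intratumoral": _HIGH, "peritumoral": _HIGH},
        "Low": {"intratumoral": _LOW, "peritumoral": _LOW},
    }


@dataclass(frozen=True)
class SurvivalParams:
    """Weibull proportional-hazards generator parameters (times in months)."""

    weibull_shape: float = 1.2
    weibull_scale: float = 90.0
    log_hr_by_class: dict = field(
        default_factory=lambda: {"High": float(np.log(2.5)), "Mix": float(np.log(1.6)), "Low": 0.0}
    )
    censoring_rate: float = 0.3
    os_residual_mean: float = 8.0  # OS = DFS + Exp(mean); guarantees DFS <= OS

    def validate(self) -> None:
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValidationError("Weibull shape/scale must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")
        for c, v in self.log_hr_by_class.items():
            if not np.isfinite(v):
                raise ValidationError(f"log HR for class {c} not finite")


def default_response_params() -> dict[str, dict[str, float]]:
    # Ordinal RECIST draw per class: Low-class cases respond most often.
    return {
        "Low": {"CR": 0.15, "PR": 0.45, "SD": 0.10, "PD": 0.30},
        "Mix": {"CR": 0.05, "PR": 0.20, "SD": 0.25, "PD": 0.50},
        "High": {"CR": 0.02, "PR": 0.06, "SD": 0.22, "PD": 0.70},
    }


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort."""

    n_cases: int = 240
    class_proportions: dict = field(
        default_factory=lambda: {"High": 1 / 3, "Mix": 1 / 3, "Low": 1 / 3}
    )
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_mm: tuple[float, float] = (6.0, 10.0)
    texture_params_per_class: dict = field(default_factory=default_texture_params)
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    response_params: dict = field(default_factory=default_response_params)
    background_mean_hu: float = 40.0
    background_sd_hu: float = 8.0
    background_correlation_mm: float = 6.0
    peritumoral_shell_mm: float = 4.0
    air_pocket_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValidationError("n_cases must be >= 1")
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValidationError("class proportions must be >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing must be positive")
        if min(self.grid_shape) < 32:
            raise ValidationError("grid must be at least 32^3")
        lo, hi = self.tumor_radius_mm
        if lo <= 0 or hi < lo:
            raise ValidationError("tumor_radius_mm must be a positive range")
        for cls, regions in self.texture_params_per_class.items():
            if cls not in ("High", "Low"):
                raise ValidationError("texture params are specified for High and Low")
            for tp in regions.values():
                tp.validate()
        self.survival_params.validate()
        for cls, probs in self.response_params.items():
            if cls not in CLASSES:
                raise ValidationError(f"unknown class {cls!r} in response_params")
            if abs(sum(probs.get(r, 0.0) for r in RESPONSES) - 1.0) > 1e-9:
                raise ValidationError(f"response probabilities for {cls} must sum to 1")


@dataclass
class ClinicalRecord:
    case_id: str
    nlr_intra: float
    nlr_peri: float
    nlr_status: str
    dfs_time: float
    dfs_event: int
    os_time: float
    os_event: int
    pfs_time: float
    pfs_event: int
    response: str
    age: float
    sex: str
    t_stage: int
    n_stage: int
    m_stage: int


@dataclass
class SyntheticCase:
    case_id: str
    volume: ImageVolume
    tumor_mask: BinaryMask
    clinical: ClinicalRecord
    latent_class: str


# ---------------------------------------------------------------------------
# Texture parameter resolution
# ---------------------------------------------------------------------------


def _region_params(
    config: CohortConfig, latent_class: str, mix_high_region: str | None
) -> dict[str, TextureParams]:
    """Texture parameters per region for one case.

    Mix cases take the High-class parameters in the region whose NLR is >= 1
    (``mix_high_region``) and the Low-class parameters in the other region,
    matching the label semantics of the Mix-1 / Mix-2 subtypes.
    """
    tp = config.texture_params_per_class
    if latent_class == "High":
        return dict(tp["High"])
    if latent_class == "Low":
        return dict(tp["Low"])
    if latent_class == "Mix":
        if mix_high_region not in ("intratumoral", "peritumoral"):
            raise ValidationError("Mix case needs its high region")
        out = {}
        for region in ("intratumoral", "peritumoral"):
            src = "High" if region == mix_high_region else "Low"
            out[region] = tp[src][region]
        return out
    raise ValidationError(f"unknown class {latent_class!r}")


def _grf(shape, spacing, corr_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary Gaussian random field.

    White noise smoothed with a Gaussian kernel of width ``corr_mm`` (mm,
    spacing-aware) and renormalized to unit sample variance.
    """
    noise = rng.standard_normal(shape)
    sigma_vox = [corr_mm / s for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------


def generate_phantom(
    config: CohortConfig,
    latent_class: str,
    seed: int,
    mix_high_region: str | None = None,
) -> tuple[ImageVolume, BinaryMask]:
    """One CT-like phantom: smooth abdominal background (~40 HU), a randomly
    perturbed ellipsoidal tumor, class-conditioned texture fields inside the
    tumor and in its 0-4 mm peritumoral shell, and an optional air pocket
    (-1000 HU) away from the tumor.

    Raises :class:`GeometryError` when the tumor cannot fit the grid with a
    4 mm margin.
    """
    if latent_class not in CLASSES:
        raise ValidationError(f"unknown class {latent_class!r}")
    if latent_class == "Mix" and mix_high_region is None:
        mix_high_region = "intratumoral"
    rng = np.random.default_rng(seed)
    shape = tuple(config.grid_shape)
    spacing = tuple(config.spacing_mm)
    extent = np.array(shape) * np.array(spacing)
    r_lo, r_hi = config.tumor_radius_mm
    margin = 4.0 + config.peritumoral_shell_mm
    if np.any(2 * (r_hi + margin) > extent):
        raise GeometryError(
            f"tumor (radius up to {r_hi} mm + {margin} mm margin) does not fit "
            f"grid extent {extent.tolist()} mm"
        )

    radii = rng.uniform(r_lo, r_hi, size=3)
    centre = extent / 2 + rng.uniform(-2.0, 2.0, size=3)
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    quad = (
        ((xx - centre[0]) / radii[0]) ** 2
        + ((yy - centre[1]) / radii[1]) ** 2
        + ((zz - centre[2]) / radii[2]) ** 2
    )
    # Smooth boundary perturbation makes the ellipsoid blobby.
    bump = _grf(shape, spacing, 3.0, rng) * 0.15
    tumor = quad + bump < 1.0
    # keep the largest connected component for a clean single tumor
    lab, nlab = ndimage.label(tumor)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
        tumor = lab == (1 + int(np.argmax(sizes)))
    if not tumor.any():
        raise GeometryError("perturbed tumor mask is empty")

    background = config.background_mean_hu + config.background_sd_hu * _grf(
        shape, spacing, config.background_correlation_mm, rng
    )
    volume = background

    dist_out = ndimage.distance_transform_edt(~tumor, sampling=spacing)
    shell = (~tumor) & (dist_out <= config.peritumoral_shell_mm)

    params = _region_params(config, latent_class, mix_high_region)
    tp_in = params["intratumoral"]
    tp_out = params["peritumoral"]
    field_in = tp_in.mean_hu + tp_in.intensity_sd_hu * _grf(
        shape, spacing, tp_in.correlation_length_mm, rng
    )
    field_out = tp_out.mean_hu + tp_out.intensity_sd_hu * _grf(
        shape, spacing, tp_out.correlation_length_mm, rng
    )
    volume = np.where(tumor, field_in, volume)
    volume = np.where(shell, field_out, volume)

    if rng.uniform() < config.air_pocket_prob:
        # a small air sphere outside tumor + shell, near a corner
        pocket_r = 3.0
        corner = np.array([0.15, 0.15, 0.15]) * extent
        d2 = ((xx - corner[0]) ** 2 + (yy - corner[1]) ** 2 + (zz - corner[2]) ** 2)
        pocket = (d2 < pocket_r**2) & ~tumor & ~shell
        volume = np.where(pocket, -1000.0, volume)

    volume = np.clip(volume, HU_MIN, HU_MAX)
    return (
        ImageVolume(volume, spacing),
        BinaryMask(tumor, spacing),
    )


# ---------------------------------------------------------------------------
# Clinical side
# ---------------------------------------------------------------------------


def nlr_status_from_values(nlr_intra: float, nlr_peri: float) -> str:
    """Label rule: High if both ratios >= 1, Low if both < 1, else Mix."""
    hi_i, hi_p = nlr_intra >= 1.0, nlr_peri >= 1.0
    if hi_i and hi_p:
        return "High"
    if not hi_i and not hi_p:
        return "Low"
    return "Mix"


def generate_nlr_values(
    latent_class: str, seed: int | np.random.Generator
) -> tuple[float, float]:
    """Draw (intratumoral, peritumoral) NLR consistent with the class.

    Neutrophil and lymphocyte counts per region are drawn from
    class-conditioned distributions: in a region meant to be "high" the
    neutrophil count is forced to at least the lymphocyte count; in a "low"
    region it is kept strictly below.  Mix cases choose the Mix-1 (intra
    high) vs Mix-2 (peri high) subtype with equal probability.
    """
    if latent_class not in CLASSES:
        raise ValidationError(f"unknown class {latent_class!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if latent_class == "High":
        high = {"intratumoral": True, "peritumoral": True}
    elif latent_class == "Low":
        high = {"intratumoral": False, "peritumoral": False}
    else:
        mix1 = rng.uniform() < 0.5
        high = {"intratumoral": mix1, "peritumoral": not mix1}
    out = {}
    for region, is_high in high.items():
        lymph = int(rng.poisson(60)) + 5
        ratio = float(np.exp(rng.normal(0.45 if is_high else -0.55, 0.35)))
        neut = int(np.ceil(ratio * lymph)) if is_high else int(np.floor(ratio * lymph))
        if is_high:
            neut = max(neut, lymph)  # guarantee ratio >= 1
        else:
            neut = min(max(neut, 0), lymph - 1)  # guarantee ratio < 1
        out[region] = neut / lymph
    return out["intratumoral"], out["peritumoral"]


def _draw_covariates(rng: np.random.Generator) -> dict:
    return {
        "age": float(np.round(rng.normal(57.0, 10.0), 1)),
        "sex": "male" if rng.uniform() < 0.68 else "female",
        "t_stage": int(rng.choice([1, 2, 3, 4], p=[0.2, 0.1, 0.15, 0.55])),
        "n_stage": int(rng.choice([0, 1, 2, 3], p=[0.42, 0.18, 0.12, 0.28])),
        "m_stage": int(rng.uniform() < 0.05),
    }


# modest covariate log-hazard effects on top of the class effect
_COV_LOG_HR = {"age_per_decade": 0.10, "t_stage": 0.15, "n_stage": 0.12, "m_stage": 0.50}


def linear_predictor(latent_class: str, covariates: dict, params: SurvivalParams) -> float:
    lp = params.log_hr_by_class.get(latent_class, 0.0)
    lp += _COV_LOG_HR["age_per_decade"] * (covariates.get("age", 57.0) - 57.0) / 10.0
    lp += _COV_LOG_HR["t_stage"] * (covariates.get("t_stage", 2) - 2)
    lp += _COV_LOG_HR["n_stage"] * covariates.get("n_stage", 0)
    lp += _COV_LOG_HR["m_stage"] * covariates.get("m_stage", 0)
    return float(lp)


def _weibull_time(lp: float, params: SurvivalParams, rng: np.random.Generator) -> float:
    u = rng.uniform()
    return float(
        params.weibull_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / params.weibull_shape)
    )


def generate_survival(
    latent_class: str,
    covariates: dict,
    config: CohortConfig,
    seed: int | np.random.Generator,
) -> tuple[float, int, float, int]:
    """Draw (dfs_time, dfs_event, os_time, os_event) in months.

    Event times come from a Weibull proportional-hazards model whose linear
    predictor combines the class effect and covariate effects; OS = DFS plus
    an exponential residual, so DFS <= OS always.  A case is censored with
    probability ``censoring_rate``; censored observation times are uniform
    on (0, T).
    """
    params = config.survival_params
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lp = linear_predictor(latent_class, covariates, params)
    dfs = _weibull_time(lp, params, rng)
    os_t = dfs + float(rng.exponential(params.os_residual_mean))
    censored = rng.uniform() < params.censoring_rate
    if censored:
        c = float(rng.uniform(0.0, os_t))
        dfs_time, dfs_event = (c, 0) if c < dfs else (dfs, 1)
        return dfs_time, dfs_event, c, 0
    return dfs, 1, os_t, 1


def generate_response(
    latent_class: str, config: CohortConfig, rng: np.random.Generator
) -> str:
    probs = config.response_params[latent_class]
    return str(rng.choice(RESPONSES, p=[probs[r] for r in RESPONSES]))


def _pfs(latent_class: str, config: CohortConfig, rng: np.random.Generator):
    # Short post-treatment horizon (months), same PH structure as DFS.
    lp = config.survival_params.log_hr_by_class.get(latent_class, 0.0)
    t = float(10.0 * (-np.log(rng.uniform()) / np.exp(lp)) ** (1 / 1.1))
    if rng.uniform() < config.survival_params.censoring_rate:
        return float(rng.uniform(0.0, t)), 0
    return t, 1


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def generate_case(config: CohortConfig, latent_class: str, case_id: str, seed: int) -> SyntheticCase:
    rng = np.random.default_rng(seed)
    nlr_i, nlr_p = generate_nlr_values(latent_class, rng)
    mix_high = None
    if latent_class == "Mix":
        mix_high = "intratumoral" if nlr_i >= 1.0 else "peritumoral"
    vol, mask = generate_phantom(
        config, latent_class, int(rng.integers(0, 2**31 - 1)), mix_high_region=mix_high
    )
    cov = _draw_covariates(rng)
    dfs_t, dfs_e, os_t, os_e = generate_survival(latent_class, cov, config, rng)
    pfs_t, pfs_e = _pfs(latent_class, config, rng)
    resp = generate_response(latent_class, config, rng)
    clinical = ClinicalRecord(
        case_id=case_id,
        nlr_intra=nlr_i,
        nlr_peri=nlr_p,
        nlr_status=nlr_status_from_values(nlr_i, nlr_p),
        dfs_time=dfs_t,
        dfs_event=dfs_e,
        os_time=os_t,
        os_event=os_e,
        pfs_time=pfs_t,
        pfs_event=pfs_e,
        response=resp,
        **cov,
    )
    assert clinical.nlr_status == latent_class
    return SyntheticCase(case_id, vol, mask, clinical, latent_class)


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> tuple[list[SyntheticCase], dict]:
    """Generate the cohort; optionally write NIfTI volumes/masks, clinical.csv
    and truth.json to ``out_dir``.

    Returns the cases plus a truth side-channel describing the planted
    signal (which texture parameters differ between classes, and the
    survival/response generators), for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    probs = [config.class_proportions.get(c, 0.0) for c in CLASSES]
    classes = rng.choice(CLASSES, size=config.n_cases, p=probs)
    case_seeds = rng.integers(0, 2**31 - 1, size=config.n_cases)
    cases = [
        generate_case(config, str(cls), f"case_{k:04d}", int(s))
        for k, (cls, s) in enumerate(zip(classes, case_seeds))
    ]
    tp = config.texture_params_per_class
    planted = {
        region: [
            f
            for f in ("correlation_length_mm", "intensity_sd_hu", "mean_hu")
            if getattr(tp["High"][region], f) != getattr(tp["Low"][region], f)
        ]
        for region in ("intratumoral", "peritumoral")
    }
    truth = {
        "seed": config.seed,
        "class_sequence": [str(c) for c in classes],
        "planted_texture_differences": planted,
        "texture_params": {
            cls: {reg: dataclasses.asdict(p) for reg, p in regions.items()}
            for cls, regions in tp.items()
        },
        "survival_params": {
            "weibull_shape": config.survival_params.weibull_shape,
            "weibull_scale": config.survival_params.weibull_scale,
            "log_hr_by_class": config.survival_params.log_hr_by_class,
            "censoring_rate": config.survival_params.censoring_rate,
        },
        "response_params": config.response_params,
    }
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            for case in cases:
                write_volume(case.volume, out / f"{case.case_id}_volume.nii.gz")
                write_mask(case.tumor_mask, out / f"{case.case_id}_mask.nii.gz")
            clinical_table(cases).to_csv(out / "clinical.csv", index=False)
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
        except OSError as err:
            raise IOError(f"cannot write cohort to {out}: {err}") from err
    return cases, truth


def clinical_table(cases: list[SyntheticCase]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c.clinical) for c in cases])
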