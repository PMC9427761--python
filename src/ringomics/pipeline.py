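"""Pipeline orchestration: simulate -> ring -> extract -> fit -> evaluate.

A run is a pure function of (YAML config, global seed): the manifest records
the config hash, the seed, and a SHA-256 checksum of every output file, so a
rerun with identical inputs yields identical checksums.  The single global
seed fans out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CLASSES, CohortConfig, SurvivalParams, TextureParams, generate_cohort
from .errors import ValidationError
from .evaluation import (
    c_index,
    cox_fit,
    km_estimate,
    logrank_test,
    response_table,
    roc_auc,
    univariate_cox_screen,
)
from .features import DEFAULT_BIN_COUNTS, catalogue_names, extract_case
from .geometry import build_peritumoral_ring, exclusion_from_hu, read_mask, read_volume
from .signature import assign_rs_group, compute_rs_table, fit_signature

# fixed per-stage seed offsets off the global seed
_STAGE_OFFSETS = {"cohort": 0, "extract": 101, "fit": 211, "evaluate": 307}


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    ring_outer_mm: float = 2.0
    ring_inner_mm: float = 1.0
    exclusion_air_hu: float = -500.0
    exclusion_vessel_hu: float = 300.0
    bin_counts: tuple[int, ...] = DEFAULT_BIN_COUNTS
    mrmr_k: int = 30
    cv_folds: int = 5
    seed: int = 0
    out_dir: Path = Path("ringomics_run")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None, out_dir=None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" not in raw:
            raise ValidationError("config is missing the required 'cohort' block")
        ch = dict(raw["cohort"])
        if "texture_params_per_class" in ch:
            ch["texture_params_per_class"] = {
                cls: {reg: TextureParams(**tp) for reg, tp in regions.items()}
                for cls, regions in ch["texture_params_per_class"].items()
            }
        if "survival_params" in ch:
            ch["survival_params"] = SurvivalParams(**ch["survival_params"])
        for key in ("grid_shape", "spacing_mm", "tumor_radius_mm"):
            if key in ch:
                ch[key] = tuple(ch[key])
        cfg = cls(cohort=CohortConfig(**ch))
        for key in (
            "ring_outer_mm", "ring_inner_mm", "exclusion_air_hu", "exclusion_vessel_hu",
            "mrmr_k", "cv_folds", "seed",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "bin_counts" in raw:
            cfg.bin_counts = tuple(raw["bin_counts"])
        if seed is not None:
            cfg.seed = seed
        if out_dir is not None:
            cfg.out_dir = Path(out_dir)
        cfg.cohort.seed = cfg.seed + _STAGE_OFFSETS["cohort"]
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def extract_cohort_features(
    cases,
    ring_outer_mm: float = 2.0,
    ring_inner_mm: float = 1.0,
    exclusion_air_hu: float = -500.0,
    exclusion_vessel_hu: float = 300.0,
    bin_counts=DEFAULT_BIN_COUNTS,
) -> pd.DataFrame:
    """Ring construction + 584-feature extraction for every case."""
    rows = {}
    for case in cases:
        try:
            excl = exclusion_from_hu(case.volume, exclusion_air_hu, exclusion_vessel_hu)
            rois = build_peritumoral_ring(
                case.tumor_mask, ring_outer_mm, ring_inner_mm, exclusion=excl
            )
            rows[case.case_id] = extract_case(case.volume, rois, bin_counts)
        except Exception as err:
            raise type(err)(f"[extract stage, case {case.case_id}] {err}") from err
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df[catalogue_names(bin_counts)]
    df.index.name = "case_id"
    return df


def evaluate_cohort(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    signature,
    seed: int = 0,
) -> dict:
    """RS scoring, ROC, KM/log-rank by RS group, Cox models and response rates."""
    clin = clinical.set_index("case_id").loc[features.index]
    rs = compute_rs_table(signature, features)
    groups = rs.map(lambda v: assign_rs_group(v, signature.tertile_cutoffs))

    out: dict = {"rs": rs, "rs_group": groups}
    hl = clin["nlr_status"].isin(["High", "Low"])
    if hl.sum() >= 4 and clin.loc[hl, "nlr_status"].nunique() == 2:
        roc = roc_auc(rs[hl], (clin.loc[hl, "nlr_status"] == "High").astype(int))
        out["roc_high_vs_low"] = roc
    notH = clin["nlr_status"].isin(["High", "Mix", "Low"])
    if clin["nlr_status"].nunique() == 3:
        roc2 = roc_auc(rs[notH], (clin.loc[notH, "nlr_status"] == "High").astype(int))
        out["roc_high_vs_rest"] = roc2

    for outcome in ("dfs", "os"):
        t, e = clin[f"{outcome}_time"], clin[f"{outcome}_event"]
        out[f"km_{outcome}"] = {
            g: km_estimate(t[groups == g], e[groups == g])
            for g in sorted(groups.unique())
            if (groups == g).sum() > 0
        }
        if e.sum() >= 1 and groups.nunique() > 1:
            out[f"logrank_{outcome}"] = logrank_test(t, e, groups)

    covs = ["rs_numeric_group", "age", "t_stage", "n_stage", "m_stage"]
    model_df = clin.copy()
    model_df["rs_numeric_group"] = groups.map({"RS-Low": 0, "RS-Middle": 1, "RS-High": 2})
    model_df["age"] = clin["age"]
    for outcome in ("dfs", "os"):
        try:
            uni, passing = univariate_cox_screen(
                model_df, covs, f"{outcome}_time", f"{outcome}_event"
            )
            out[f"cox_univariate_{outcome}"] = uni
            if passing:
                out[f"cox_multivariate_{outcome}"] = cox_fit(
                    model_df, passing, f"{outcome}_time", f"{outcome}_event",
                    c_index_bootstrap=200, seed=seed,
                )
        except (ValidationError, Exception):
            pass

    if "response" in clin.columns and clin["response"].notna().all():
        out["response"] = response_table(clin["response"], groups, rs)
        ci, ci_ci = c_index(
            rs.to_numpy(), clin["pfs_time"].to_numpy(), clin["pfs_event"].to_numpy(),
            n_bootstrap=200, seed=seed,
        )
        out["c_index_rs_pfs"] = (ci, ci_ci)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    cohort_cfg = config.cohort
    cohort_cfg.seed = config.seed + _STAGE_OFFSETS["cohort"]
    cases, truth = generate_cohort(cohort_cfg, out_dir=out / "cohort")

    features = extract_cohort_features(
        cases,
        config.ring_outer_mm,
        config.ring_inner_mm,
        config.exclusion_air_hu,
        config.exclusion_vessel_hu,
        config.bin_counts,
    )
    features.to_csv(out / "features.csv")

    clinical = pd.read_csv(out / "cohort" / "clinical.csv")
    status = clinical.set_index("case_id")["nlr_status"]
    signature = fit_signature(
        features, status, k=config.mrmr_k, folds=config.cv_folds,
        seed=config.seed + _STAGE_OFFSETS["fit"],
    )
    signature.to_json(out / "signature.json")

    results = evaluate_cohort(
        features, clinical, signature, seed=config.seed + _STAGE_OFFSETS["evaluate"]
    )
    _write_evaluation_csvs(results, out)

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_fingerprint(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_cases": len(cases),
        "elapsed_s": round(time.time() - t0, 2),
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_fingerprint(config: RunConfig) -> dict:
    def enc(obj):
        if isinstance(obj, (CohortConfig, SurvivalParams, TextureParams)):
            return {k: enc(v) for k, v in vars(obj).items()}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return {k: enc(v) for k, v in vars(config).items() if k != "out_dir"}


def _write_evaluation_csvs(results: dict, out: Path) -> None:
    rows = pd.DataFrame({"rs": results["rs"], "rs_group": results["rs_group"]})
    rows.to_csv(out / "rs.csv")
    if "roc_high_vs_low" in results:
        roc = results["roc_high_vs_low"]
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(out / "roc.csv", index=False)
    km_rows = []
    for outcome in ("dfs", "os"):
        for g, curve in results.get(f"km_{outcome}", {}).items():
            for t, s in zip(curve.times, curve.survival):
                km_rows.append({"outcome": outcome, "group": g, "time": t, "survival": s})
    if km_rows:
        pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False)
    for outcome in ("dfs", "os"):
        if f"cox_univariate_{outcome}" in results:
            results[f"cox_univariate_{outcome}"].to_csv(out / f"cox_univariate_{outcome}.csv")
        if f"cox_multivariate_{outcome}" in results:
            results[f"cox_multivariate_{outcome}"].table.to_csv(
                out / f"cox_multivariate_{outcome}.csv"
            )
    if "response" in results:
        pd.DataFrame(results["response"]["rates"]).T.to_csv(out / "response_rates.csv")


# ---------------------------------------------------------------------------
# Input validation (reporting, never raising)
# ---------------------------------------------------------------------------


def validate_inputs(volume_dir: str | Path, clinical_csv: str | Path) -> list[dict]:
    """Check grid alignment, mask binarity and clinical schema; returns a
    machine-readable problem list (empty when clean)."""
    problems: list[dict] = []
    vol_dir = Path(volume_dir)
    clinical = pd.read_csv(clinical_csv)
    required = {
        "case_id", "nlr_intra", "nlr_peri", "nlr_status",
        "dfs_time", "dfs_event", "os_time", "os_event",
    }
    missing_cols = required - set(clinical.columns)
    if missing_cols:
        problems.append({"kind": "schema", "detail": f"missing columns {sorted(missing_cols)}"})
        return problems
    for _, row in clinical.iterrows():
        cid = row["case_id"]
        for col in ("dfs_time", "os_time"):
            if row[col] < 0:
                problems.append({"kind": "negative_time", "case_id": cid, "column": col})
        for col in ("dfs_event", "os_event"):
            if row[col] not in (0, 1):
                problems.append({"kind": "bad_event_flag", "case_id": cid, "column": col})
        if row["nlr_status"] not in CLASSES:
            problems.append({"kind": "bad_nlr_status", "case_id": cid})
        vpath = vol_dir / f"{cid}_volume.nii.gz"
        mpath = vol_dir / f"{cid}_mask.nii.gz"
        if not vpath.exists() or not mpath.exists():
            problems.append({"kind": "missing_file", "case_id": cid})
            continue
        try:
            vol = read_volume(vpath)
            read_mask(mpath, vol)
        except Exception as err:
            problems.append({"kind": "geometry", "case_id": cid, "detail": str(err)})
    return problems
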