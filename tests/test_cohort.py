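"""Synthetic cohort generator: phantoms, NLR labels, survival, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from ringomics.cohort import (
    CLASSES,
    CohortConfig,
    SurvivalParams,
    TextureParams,
    generate_case,
    generate_cohort,
    generate_nlr_values,
    generate_phantom,
    generate_survival,
    nlr_status_from_values,
)
from ringomics.errors import GeometryError, ValidationError

from .oracles import semivariogram_range


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            CohortConfig(class_proportions={"High": 0.5, "Mix": 0.2, "Low": 0.2})

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(grid_shape=(16, 48, 48))

    def test_bad_response_probs_rejected(self):
        bad = {"High": {"CR": 0.5, "PR": 0.5, "SD": 0.5, "PD": 0.0}}
        with pytest.raises(ValidationError):
            CohortConfig(response_params=bad)


class TestPhantom:
    def test_identical_seed_bit_identical(self, small_config):
        v1, m1 = generate_phantom(small_config, "High", seed=5)
        v2, m2 = generate_phantom(small_config, "High", seed=5)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_zero_texture_sd_gives_constant_tumor_interior(self):
        flat = TextureParams(2.0, 0.0, 45.0)
        cfg = CohortConfig(
            texture_params_per_class={
                "High": {"intratumoral": flat, "peritumoral": flat},
                "Low": {"intratumoral": flat, "peritumoral": flat},
            }
        )
        vol, mask = generate_phantom(cfg, "High", seed=3)
        assert np.allclose(vol.voxels[mask.voxels], 45.0)

    def test_tumor_not_fitting_raises_geometry_error(self):
        cfg = CohortConfig(grid_shape=(32, 32, 32), tumor_radius_mm=(14.0, 15.0))
        with pytest.raises(GeometryError):
            generate_phantom(cfg, "Low", seed=0)

    def test_correlation_length_orders_semivariogram_range(self):
        def cfg_with(corr):
            tp = TextureParams(corr, 15.0, 45.0)
            return CohortConfig(
                grid_shape=(48, 48, 48),
                texture_params_per_class={
                    "High": {"intratumoral": tp, "peritumoral": tp},
                    "Low": {"intratumoral": tp, "peritumoral": tp},
                },
            )

        long_r, short_r = [], []
        for seed in range(5):
            v_l, m_l = generate_phantom(cfg_with(4.0), "High", seed=seed)
            v_s, m_s = generate_phantom(cfg_with(1.0), "High", seed=seed)
            long_r.append(semivariogram_range(v_l.voxels, m_l.voxels))
            short_r.append(semivariogram_range(v_s.voxels, m_s.voxels))
        assert np.mean(long_r) > np.mean(short_r)

    def test_hu_clamped_to_ct_range(self, small_config):
        for seed in range(5):
            vol, _ = generate_phantom(small_config, "Mix", seed=seed)
            assert vol.voxels.min() >= -1024.0
            assert vol.voxels.max() <= 3071.0


class TestNlrValues:
    def test_high_class_both_ratios_at_least_one(self):
        for seed in range(50):
            i, p = generate_nlr_values("High", seed)
            assert i >= 1.0 and p >= 1.0

    def test_low_class_both_ratios_below_one(self):
        for seed in range(50):
            i, p = generate_nlr_values("Low", seed)
            assert i < 1.0 and p < 1.0

    def test_mix_subtypes_split_evenly(self):
        rng = np.random.default_rng(99)
        n = 10_000
        intra_high = 0
        for _ in range(n):
            i, p = generate_nlr_values("Mix", rng)
            assert (i >= 1.0) != (p >= 1.0)
            intra_high += i >= 1.0
        # binomial: |X/n - 0.5| within 3 SDs
        assert abs(intra_high / n - 0.5) <= 3 * 0.5 / np.sqrt(n)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            generate_nlr_values("Medium", 0)

    def test_label_rule_boundary(self):
        assert nlr_status_from_values(1.0, 1.0) == "High"
        assert nlr_status_from_values(0.99, 1.0) == "Mix"
        assert nlr_status_from_values(0.0, 0.0) == "Low"


class TestSurvival:
    def test_zero_censoring_all_events(self):
        cfg = CohortConfig(survival_params=SurvivalParams(censoring_rate=0.0))
        for seed in range(30):
            dfs_t, dfs_e, os_t, os_e = generate_survival("Mix", {}, cfg, seed)
            assert dfs_e == 1 and os_e == 1
            assert dfs_t <= os_t

    def test_dfs_never_exceeds_os(self, small_config):
        for seed in range(50):
            dfs_t, _, os_t, _ = generate_survival("High", {}, small_config, seed)
            assert dfs_t <= os_t

    def test_cox_recovers_planted_class_hazard_ratio(self):
        # n = 2000, High log-HR = log(2) vs Low: fitted HR within [1.8, 2.2]
        cfg = CohortConfig(
            survival_params=SurvivalParams(
                log_hr_by_class={"High": float(np.log(2)), "Mix": 0.3, "Low": 0.0}
            )
        )
        rng = np.random.default_rng(7)
        rows = []
        for k in range(2000):
            cls = "High" if k % 2 == 0 else "Low"
            t, e, _, _ = generate_survival(cls, {}, cfg, rng)
            rows.append({"x": int(cls == "High"), "t": t, "e": e})
        df = pd.DataFrame(rows)
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        hr = float(np.exp(cph.params_["x"]))
        se = float(cph.standard_errors_["x"])
        assert 1.8 <= hr <= 2.2
        assert abs(cph.params_["x"] - np.log(2)) <= 3 * se

    def test_null_model_logrank_not_significant_on_average(self):
        from ringomics.evaluation import logrank_test

        cfg = CohortConfig(
            survival_params=SurvivalParams(
                log_hr_by_class={"High": 0.0, "Mix": 0.0, "Low": 0.0}
            )
        )
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(20):
            times, events, groups = [], [], []
            for k in range(120):
                cls = CLASSES[k % 3]
                t, e, _, _ = generate_survival(cls, {}, cfg, rng)
                times.append(t)
                events.append(e)
                groups.append(cls)
            pvals.append(logrank_test(times, events, groups)[1])
        # under the null, p-values are ~uniform: mean near 0.5, some spread
        assert 0.25 < np.mean(pvals) < 0.75
        assert min(pvals) < 0.5 < max(pvals)


class TestCohortAssembly:
    def test_class_sequence_reproducible(self, small_config):
        cases1, truth1 = generate_cohort(small_config)
        cases2, truth2 = generate_cohort(small_config)
        assert truth1["class_sequence"] == truth2["class_sequence"]
        np.testing.assert_array_equal(
            cases1[0].volume.voxels, cases2[0].volume.voxels
        )

    def test_label_consistency_and_clinical_schema(self, small_config):
        cases, _ = generate_cohort(small_config)
        for case in cases:
            c = case.clinical
            assert nlr_status_from_values(c.nlr_intra, c.nlr_peri) == case.latent_class
            assert c.nlr_status == case.latent_class
            assert c.dfs_time >= 0 and c.os_time >= c.dfs_time
            assert c.response in ("CR", "PR", "SD", "PD")

    def test_multinomial_class_counts(self):
        cfg = CohortConfig(n_cases=240, grid_shape=(32, 32, 32), seed=4)
        rng = np.random.default_rng(cfg.seed)
        classes = rng.choice(CLASSES, size=240, p=[1 / 3] * 3)
        # counts within 3 SDs of 80 (multinomial marginal)
        sd = np.sqrt(240 * (1 / 3) * (2 / 3))
        for c in CLASSES:
            assert abs((classes == c).sum() - 80) <= 3 * sd

    def test_degenerate_proportions_all_high(self):
        cfg = CohortConfig(
            n_cases=5, class_proportions={"High": 1.0, "Mix": 0.0, "Low": 0.0}, seed=2
        )
        cases, _ = generate_cohort(cfg)
        assert all(c.latent_class == "High" for c in cases)

    def test_cohort_written_to_disk(self, tmp_path):
        cfg = CohortConfig(n_cases=2, seed=8)
        generate_cohort(cfg, out_dir=tmp_path / "coh")
        assert (tmp_path / "coh" / "clinical.csv").exists()
        assert (tmp_path / "coh" / "truth.json").exists()
        assert (tmp_path / "coh" / "case_0000_volume.nii.gz").exists()
        df = pd.read_csv(tmp_path / "coh" / "clinical.csv")
        assert set(df.columns) >= {
            "case_id", "nlr_intra", "nlr_peri", "nlr_status",
            "dfs_time", "dfs_event", "os_time", "os_event",
            "pfs_time", "pfs_event", "response",
            "age", "sex", "t_stage", "n_stage", "m_stage",
        }
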