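"""ROC/AUC, Kaplan-Meier, log-rank, Cox, C-index, nomogram and response tables."""

import numpy as np
import pandas as pd
import pytest

from ringomics.errors import ConvergenceError, ValidationError
from ringomics.evaluation import (
    c_index,
    cox_fit,
    km_estimate,
    logrank_test,
    nomogram_score,
    response_table,
    roc_auc,
    univariate_cox_screen,
)

from .oracles import brute_auc, brute_c_index, brute_cox_coef


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.ci_low <= r.auc <= r.ci_high

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        r = roc_auc(rng.normal(size=n), rng.integers(0, 2, size=n))
        assert abs(r.auc - 0.5) < 0.02

    def test_hand_example_matches_pair_counting(self):
        scores = [3.0, 1.0, 2.0, 2.0, 0.5, 2.5]
        labels = [1, 0, 1, 0, 0, 1]
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_auc(scores, labels))

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_delong_ci_covers_truth_reasonably(self):
        # repeated binormal samples: ~95% of CIs should cover the true AUC
        rng = np.random.default_rng(11)
        mu = 1.0
        true_auc = 0.760250  # Phi(mu / sqrt(2))
        covered = 0
        reps = 200
        for _ in range(reps):
            pos = rng.normal(mu, 1, 60)
            neg = rng.normal(0, 1, 60)
            r = roc_auc(np.r_[pos, neg], np.r_[np.ones(60), np.zeros(60)])
            covered += r.ci_low <= true_auc <= r.ci_high
        assert 0.90 <= covered / reps <= 0.99


class TestKaplanMeier:
    def test_no_censoring_reduces_to_ecdf(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        curve = km_estimate(times, [1] * 5)
        for k, t in enumerate(times):
            assert curve.at(t) == pytest.approx(1 - (k + 1) / 5)

    def test_textbook_product_limit_example(self):
        # times 1, 2+, 3, 4+, 5: S(3) = (4/5)(2/3) = 0.5333
        curve = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        assert curve.at(3.0) == pytest.approx((4 / 5) * (2 / 3))
        assert curve.at(1.0) == pytest.approx(4 / 5)

    def test_all_censored_flat_curve_and_logrank_error(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [0, 0], ["a", "b"])

    def test_logrank_null_pvalues_spread_uniformly(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(40):
            t = rng.exponential(10, 80)
            g = np.repeat(["a", "b"], 40)
            pvals.append(logrank_test(t, np.ones(80, int), g)[1])
        assert 0.3 < np.mean(pvals) < 0.7


class TestCox:
    def hand_dataset(self):
        # 8 subjects, binary covariate, distinct times
        return pd.DataFrame(
            {
                "x": [1, 1, 1, 1, 0, 0, 0, 0],
                "t": [2.0, 4.0, 5.0, 9.0, 3.0, 7.0, 11.0, 14.0],
                "e": [1, 1, 0, 1, 1, 1, 0, 1],
            }
        )

    def test_coefficient_matches_brute_force_partial_likelihood(self):
        df = self.hand_dataset()
        res = cox_fit(df, ["x"], "t", "e")
        beta_oracle = brute_cox_coef(df["x"], df["t"], df["e"])
        assert res.coef("x") == pytest.approx(beta_oracle, abs=1e-4)

    def test_duplicating_subjects_preserves_hazard_ratio(self):
        # exact invariance holds for the Breslow partial likelihood; the
        # Efron tie correction perturbs it only slightly
        df = self.hand_dataset()
        dup = pd.concat([df, df], ignore_index=True)
        b1 = brute_cox_coef(df["x"], df["t"], df["e"])
        b2 = brute_cox_coef(dup["x"], dup["t"], dup["e"])
        assert b2 == pytest.approx(b1, abs=1e-4)
        res1 = cox_fit(df, ["x"], "t", "e")
        res2 = cox_fit(dup, ["x"], "t", "e")
        assert res2.table.loc["x", "hr"] == pytest.approx(
            res1.table.loc["x", "hr"], rel=0.15
        )

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(21)
        covered = 0
        reps = 60
        for _ in range(reps):
            n = 300
            df = pd.DataFrame(
                {
                    "x": rng.integers(0, 2, n),
                    "t": rng.exponential(10, n),
                    "e": np.ones(n, int),
                }
            )
            res = cox_fit(df, ["x"], "t", "e")
            covered += res.table.loc["x", "ci_low"] <= 1.0 <= res.table.loc["x", "ci_high"]
        assert covered / reps >= 0.85

    def test_logrank_agrees_with_cox_score_test_direction(self):
        # for one binary covariate the log-rank chi-square equals the Cox
        # score test; check the chi-squares match closely on event-only data
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(2)
        n = 120
        x = rng.integers(0, 2, n)
        t = rng.exponential(10 * np.exp(-0.7 * x))
        chi_lr = multivariate_logrank_test(t, x, np.ones(n, int)).test_statistic
        df = pd.DataFrame({"x": x, "t": t, "e": np.ones(n, int)})
        cph_res = cox_fit(df, ["x"], "t", "e")
        wald_chi = (cph_res.coef("x") / cph_res.table.loc["x", "se"]) ** 2
        # score and Wald tests are asymptotically equivalent
        assert chi_lr == pytest.approx(wald_chi, rel=0.25)

    def test_event_free_data_rejected(self):
        df = pd.DataFrame({"x": [0, 1], "t": [1.0, 2.0], "e": [0, 0]})
        with pytest.raises(ValidationError):
            cox_fit(df, ["x"], "t", "e")

    def test_univariate_screen_flags_significant_covariates(self):
        rng = np.random.default_rng(4)
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        t = rng.exponential(10 * np.exp(-1.0 * x1))
        df = pd.DataFrame({"x1": x1, "x2": x2, "t": t, "e": np.ones(n, int)})
        table, passing = univariate_cox_screen(df, ["x1", "x2"], "t", "e")
        assert "x1" in passing
        assert "x2" not in passing


class TestCIndex:
    def test_perfect_predictor(self):
        t = np.array([5.0, 3.0, 9.0, 1.0])
        ci, _ = c_index(-t, t, np.ones(4, int), n_bootstrap=0)
        assert ci == 1.0

    def test_random_predictor_near_half(self):
        rng = np.random.default_rng(6)
        n = 3000
        ci, _ = c_index(rng.normal(size=n), rng.exponential(5, n), np.ones(n, int), n_bootstrap=0)
        assert abs(ci - 0.5) < 0.03

    def test_matches_pair_enumeration_with_censoring_and_ties(self):
        rng = np.random.default_rng(9)
        lp = rng.integers(0, 4, 30).astype(float)  # ties in predictor
        t = rng.integers(1, 10, 30).astype(float)  # ties in time
        e = rng.integers(0, 2, 30)
        e[:3] = 1
        ci, _ = c_index(lp, t, e, n_bootstrap=0)
        assert ci == pytest.approx(brute_c_index(lp, t, e))

    def test_bootstrap_ci_brackets_point(self):
        rng = np.random.default_rng(10)
        n = 150
        lp = rng.normal(size=n)
        t = rng.exponential(np.exp(-lp))
        ci, (lo, hi) = c_index(lp, t, np.ones(n, int), n_bootstrap=200, seed=1)
        assert lo <= ci <= hi
        assert hi - lo < 0.2

    def test_model_linear_predictor_beats_single_covariates(self):
        # data simulated from a two-covariate Cox model: the fitted linear
        # predictor should out-rank either covariate alone, on average
        rng = np.random.default_rng(14)
        wins = 0
        for _ in range(20):
            n = 250
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            t = rng.exponential(np.exp(-(0.8 * x1 + 0.8 * x2)))
            df = pd.DataFrame({"x1": x1, "x2": x2, "t": t, "e": np.ones(n, int)})
            res = cox_fit(df, ["x1", "x2"], "t", "e")
            lp = res.coef("x1") * x1 + res.coef("x2") * x2
            c_model, _ = c_index(lp, t, np.ones(n, int), n_bootstrap=0)
            c_x1, _ = c_index(x1, t, np.ones(n, int), n_bootstrap=0)
            c_x2, _ = c_index(x2, t, np.ones(n, int), n_bootstrap=0)
            wins += c_model >= max(c_x1, c_x2)
        assert wins >= 18


class TestNomogram:
    def fitted_model(self):
        rng = np.random.default_rng(17)
        n = 500
        rs = rng.normal(size=n)
        stage = rng.integers(1, 5, n).astype(float)
        t = rng.exponential(np.exp(-(0.9 * rs + 0.45 * stage)))
        df = pd.DataFrame({"rs": rs, "stage": stage, "t": t, "e": np.ones(n, int)})
        res = cox_fit(df, ["rs", "stage"], "t", "e")
        ranges = {"rs": (-3.0, 3.0), "stage": (1.0, 4.0)}
        return res, ranges

    def test_reference_record_scores_zero_points(self):
        res, ranges = self.fitted_model()
        pts, _ = nomogram_score(res, {"rs": -3.0, "stage": 1.0}, ranges)
        assert pts == pytest.approx(0.0)

    def test_largest_effect_extreme_scores_100(self):
        res, ranges = self.fitted_model()
        spans = {c: abs(res.coef(c)) * (ranges[c][1] - ranges[c][0]) for c in ranges}
        biggest = max(spans, key=spans.get)
        record = {"rs": -3.0, "stage": 1.0}
        record[biggest] = ranges[biggest][1]
        pts, _ = nomogram_score(res, record, ranges)
        assert pts == pytest.approx(100.0)

    def test_points_linear_in_rs(self):
        res, ranges = self.fitted_model()
        p1, lp1 = nomogram_score(res, {"rs": 0.0, "stage": 2.0}, ranges)
        p2, lp2 = nomogram_score(res, {"rs": 1.0, "stage": 2.0}, ranges)
        p3, lp3 = nomogram_score(res, {"rs": 2.0, "stage": 2.0}, ranges)
        assert p3 - p2 == pytest.approx(p2 - p1)
        assert lp3 - lp2 == pytest.approx(lp2 - lp1)
        assert (p2 > p1) == (lp2 > lp1)

    def test_missing_covariate_rejected(self):
        res, ranges = self.fitted_model()
        with pytest.raises(ValidationError):
            nomogram_score(res, {"rs": 0.0}, ranges)


class TestResponseTable:
    def test_all_pd_gives_zero_or_rate(self):
        responses = pd.Series(["PD"] * 12)
        groups = pd.Series(["RS-Low"] * 6 + ["RS-High"] * 6)
        out = response_table(responses, groups)
        assert out["rates"]["RS-Low"]["or_rate"] == 0.0
        assert out["rates"]["RS-High"]["pd_rate"] == 100.0

    def test_hand_rate_arithmetic(self):
        # 14 objective responses out of 23 -> 60.9%
        responses = pd.Series(["PR"] * 14 + ["PD"] * 9)
        groups = pd.Series(["RS-Low"] * 23)
        out = response_table(responses, groups)
        assert out["rates"]["RS-Low"]["or_rate"] == pytest.approx(60.9, abs=0.05)

    def test_identical_rs_samples_t_test_p_near_one(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        rs = pd.Series(np.r_[x, x])
        responses = pd.Series(["PR"] * 40 + ["PD"] * 40)
        groups = pd.Series(["RS-Low"] * 80)
        out = response_table(responses, groups, rs)
        assert out["rs_ttests"]["OR_vs_PD"]["p"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_reports_nan_not_zero(self):
        responses = pd.Series(["PR", "PD"])
        groups = pd.Series(["RS-Low", "RS-Low"])
        out = response_table(responses, groups)
        assert "RS-High" not in out["rates"]  # absent, never fabricated as 0

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError):
            response_table(pd.Series(["XX"]), pd.Series(["RS-Low"]))
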