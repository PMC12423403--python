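"""Estimator semantics: exact-model limits, hand-computed interpolation
values, degenerate-design refusals, weight invariance, and
outlier-robustness constructions."""

import numpy as np
import pytest

from targetmr.harmonization import harmonize
from targetmr.mr_core import (
    egger,
    ivw,
    presso,
    raps,
    robust_ivw,
    scale_to_unit_decrease,
    weighted_median,
    weighted_mode,
)
from targetmr.synthetic_gwas import make_truth, simulate_ld_panel, simulate_two_sample

from conftest import make_hset


def _simulated_hset(truth, panel_seed=0, n_panel=None):
    panel = simulate_ld_panel(n_panel or truth.k, 1, 0.0, seed=panel_seed)
    exposure, outcome = simulate_two_sample(truth, panel)
    return harmonize(exposure, outcome, panel)


class TestIVW:
    def test_single_snp_falls_back_to_wald_ratio(self):
        h = make_hset([0.5], [0.01], [0.1], [0.05])
        res = ivw(h)
        assert res.method == "wald_ratio"
        assert res.estimate == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)

    def test_exact_model_recovers_theta_with_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        h = make_hset(bx, 0.01, 0.4 * bx, [0.02, 0.05, 0.01, 0.03])
        res = ivw(h)
        assert res.estimate == pytest.approx(0.4)
        assert res.extras["q"] == pytest.approx(0.0, abs=1e-20)

    def test_weight_invariance_under_duplication(self):
        """Splitting one SNP into two half-weight copies (se_y * sqrt 2)
        leaves the IVW estimate unchanged."""
        bx = np.array([0.1, 0.2, 0.3])
        sy = np.array([0.02, 0.03, 0.04])
        by = np.array([0.05, 0.07, 0.13])
        h1 = make_hset(bx, 0.01, by, sy)
        bx2 = np.concatenate([bx[:2], [bx[2], bx[2]]])
        by2 = np.concatenate([by[:2], [by[2], by[2]]])
        sy2 = np.concatenate([sy[:2], [sy[2] * np.sqrt(2)] * 2])
        h2 = make_hset(bx2, 0.01, by2, sy2)
        assert abs(ivw(h1, "fixed").estimate - ivw(h2, "fixed").estimate) < 1e-10

    def test_model_selection_auto(self):
        bx = np.linspace(0.1, 0.3, 3)
        h3 = make_hset(bx, 0.01, 0.4 * bx + [0.01, -0.02, 0.01], 0.02)
        assert ivw(h3).extras["model"] == "fixed"
        bx = np.linspace(0.1, 0.3, 5)
        h5 = make_hset(bx, 0.01, 0.4 * bx + [0.01, -0.02, 0.01, 0.0, 0.02], 0.02)
        assert ivw(h5).extras["model"] == "random"

    def test_monte_carlo_recovery(self):
        ests = [
            ivw(_simulated_hset(make_truth(50, 0.3, seed=s, n_case=25_000, n_control=25_000)))
            .estimate
            for s in range(60)
        ]
        assert np.mean(ests) == pytest.approx(0.3, abs=0.02)


class TestEgger:
    def test_exact_model_slope_theta_intercept_zero(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        h = make_hset(bx, 0.01, 0.4 * bx, [0.02, 0.05, 0.01, 0.03, 0.02])
        res = egger(h)
        assert res.estimate == pytest.approx(0.4, abs=1e-10)
        assert res.extras["egger_intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_beta_x_refused(self):
        h = make_hset([0.1] * 4, 0.01, [0.04, 0.05, 0.03, 0.04], 0.02)
        with pytest.raises(ValueError, match="unidentified"):
            egger(h)

    def test_directional_pleiotropy_slope_and_intercept(self):
        """alpha ~ N(0.1, 0.01^2) with InSIDE: the slope stays at theta and
        the intercept estimates the mean direct effect."""
        slopes, intercepts = [], []
        for s in range(40):
            truth = make_truth(
                100, 0.3, pleiotropy="directional",
                pleiotropy_mean=0.1, pleiotropy_scale=0.01, seed=300 + s,
            )
            res = egger(_simulated_hset(truth, panel_seed=1))
            slopes.append(res.estimate)
            intercepts.append(res.extras["egger_intercept"])
        for values, target in ((slopes, 0.3), (intercepts, 0.1)):
            mc_se = np.std(values, ddof=1) / np.sqrt(len(values))
            assert abs(np.mean(values) - target) < 3 * mc_se + 1e-3


class TestWeightedMedian:
    def test_hand_interpolation_equal_weights(self):
        # ratios (1,1,1,2,3): cumulative-weight crossing sits inside the 1s
        h = make_hset(np.ones(5), 0.01, [1.0, 1.0, 1.0, 2.0, 3.0], np.ones(5))
        assert weighted_median(h, n_boot=0).estimate == pytest.approx(1.0)

    def test_hand_interpolation_unequal_weights(self):
        # ratios (1,2,3,4), weights prop to (1,2,3,4) after normalization:
        # s = (0.05, 0.2, 0.45, 0.8); estimate = 3 + (0.5-0.45)/0.35 = 3.142857
        bx = np.ones(4)
        by = np.array([1.0, 2.0, 3.0, 4.0])
        sy = 1.0 / np.sqrt([1.0, 2.0, 3.0, 4.0])
        h = make_hset(bx, 0.01, by, sy)
        assert weighted_median(h, n_boot=0).estimate == pytest.approx(3.142857, abs=1e-5)

    def test_identical_ratios_returned_exactly(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_hset(bx, 0.01, 0.6 * bx, 0.02)
        res = weighted_median(h, n_boot=200, seed=1)
        assert res.estimate == pytest.approx(0.6)

    def test_majority_valid_consistency(self):
        """60% valid instruments at theta = 0.5, 40% with ratio bias +1.

        Majority-valid consistency is an asymptotic property: the crossing
        point sits at an upper quantile of the valid cluster, so the bias
        vanishes only as the per-ratio noise does. Test in the
        strong-instrument regime (large outcome GWAS)."""
        ests = []
        for s in range(40):
            truth = make_truth(50, 0.5, n_outcome=5_000_000, seed=500 + s)
            truth.alpha[:20] = truth.gamma[:20]  # ratio bias +1 on 40%
            ests.append(weighted_median(_simulated_hset(truth), n_boot=0).estimate)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.5) < 3 * mc_se + 5e-3

    def test_bootstrap_reproducible(self):
        bx = np.linspace(0.1, 0.3, 5)
        h = make_hset(bx, 0.01, 0.4 * bx + 0.01, 0.02)
        r1 = weighted_median(h, n_boot=500, seed=42)
        r2 = weighted_median(h, n_boot=500, seed=42)
        assert r1.se == r2.se


class TestWeightedMode:
    def test_tight_cluster_dominates_outliers(self):
        by = np.array([0.4, 0.41, 0.39, 0.40, 0.42, 3.0, -2.0])
        h = make_hset(np.ones(7), 0.01, by, 0.1)
        assert weighted_mode(h, n_boot=0).estimate == pytest.approx(0.4, abs=0.05)

    def test_all_equal_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_hset(bx, 0.01, 0.25 * bx, 0.02)
        assert weighted_mode(h, n_boot=0).estimate == pytest.approx(0.25)

    def test_symmetric_tie_broken_to_smaller_and_flagged(self):
        by = np.array([0.0, 0.0, 1.0, 1.0])
        h = make_hset(np.ones(4), 0.01, by, 0.05)
        res = weighted_mode(h, n_boot=0)
        assert res.estimate < 0.5
        assert res.extras["mode_tie"]

    def test_larger_weight_cluster_wins(self):
        by = np.array([0.0, 0.0, 1.0, 1.0])
        sy = np.array([0.05, 0.05, 0.02, 0.02])  # heavier weight at 1
        h = make_hset(np.ones(4), 0.01, by, sy)
        res = weighted_mode(h, n_boot=0)
        assert res.estimate == pytest.approx(1.0, abs=0.1)


class TestRobustIVW:
    def test_matches_ivw_without_outliers(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        h = make_hset(bx, 0.01, 0.4 * bx, 0.02)  # zero residuals
        assert robust_ivw(h).estimate == pytest.approx(ivw(h, "fixed").estimate, abs=1e-6)

    def test_two_identical_snps_equal_pooled_wald(self):
        h = make_hset([0.2, 0.2], 0.01, [0.08, 0.08], 0.02)
        assert robust_ivw(h).estimate == pytest.approx(0.4)

    def test_outlier_downweighted(self):
        rng = np.random.default_rng(7)
        wins = 0
        for s in range(50):
            truth = make_truth(21, 0.3, pleiotropy="outlier", outlier_alpha=2.0, seed=700 + s)
            h = _simulated_hset(truth)
            err_robust = abs(robust_ivw(h).estimate - 0.3)
            err_plain = abs(ivw(h).estimate - 0.3)
            wins += err_robust < err_plain
        assert wins >= 45  # >= 90% on this reduced batch


class TestRAPS:
    def test_identity_psi_no_overdispersion_matches_ivw_limit(self):
        bx = np.array([0.12, 0.2, 0.31, 0.15, 0.22])
        by = 0.4 * bx + np.array([0.003, -0.004, 0.002, 0.0, -0.002])
        h = make_hset(bx, 1e-8, by, 0.02)  # se_x -> 0
        res = raps(h, overdispersion=False, psi="identity")
        assert res.estimate == pytest.approx(ivw(h, "fixed").estimate, abs=1e-8)

    def test_exact_model_recovers_theta_with_zero_tau2(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        h = make_hset(bx, 0.01, 0.4 * bx, 0.02)
        res = raps(h)
        assert res.estimate == pytest.approx(0.4, abs=1e-6)
        assert res.extras["tau2"] == pytest.approx(0.0, abs=1e-10)

    def test_overdispersion_recovery(self):
        """Balanced pleiotropy alpha ~ N(0, 0.05^2) shows up as tau^2."""
        tau2s = []
        for s in range(30):
            truth = make_truth(
                100, 0.3, pleiotropy="balanced", pleiotropy_scale=0.05, seed=900 + s
            )
            tau2s.append(raps(_simulated_hset(truth)).extras["tau2"])
        mc_se = np.std(tau2s, ddof=1) / np.sqrt(len(tau2s))
        assert abs(np.mean(tau2s) - 0.0025) < 3 * mc_se + 2e-4


class TestPRESSO:
    def test_too_few_snps_refused(self):
        bx = np.linspace(0.1, 0.3, 3)
        h = make_hset(bx, 0.01, 0.4 * bx, 0.02)
        with pytest.raises(ValueError, match="at least 4"):
            presso(h)

    def test_corrected_estimate_equals_ivw_on_reduced_set(self):
        # moderate outlier: flagged alone, leaving clean SNPs in place
        truth = make_truth(20, 0.3, seed=11)
        truth.alpha[7] = 0.3
        h = _simulated_hset(truth)
        res = presso(h, n_sim=500, seed=1)
        assert res.extras["outlier_ids"], "planted outlier not flagged"
        reduced = h.drop(res.extras["outlier_ids"])
        assert res.estimate == pytest.approx(ivw(reduced, "fixed").estimate, abs=1e-12)

    def test_clean_data_high_global_p(self):
        bx = np.linspace(0.1, 0.3, 10)
        h = make_hset(bx, 0.005, 0.4 * bx, 0.02)  # zero residuals
        res = presso(h, n_sim=500, seed=2)
        assert res.extras["presso_global_p"] > 0.5
        assert res.extras["outlier_ids"] == []

    def test_reproducible_given_seed(self):
        truth = make_truth(15, 0.2, seed=13)
        h = _simulated_hset(truth)
        r1 = presso(h, n_sim=300, seed=5)
        r2 = presso(h, n_sim=300, seed=5)
        assert r1.extras["presso_global_p"] == r2.extras["presso_global_p"]


class TestScaling:
    def test_sign_flip_and_or(self):
        res = ivw(make_hset([0.5], [0.01], [0.15], [0.05]))
        scaled = scale_to_unit_decrease(res, 1.0)
        assert scaled.estimate == pytest.approx(-0.3)
        assert scaled.odds_ratio == pytest.approx(0.741, abs=1e-3)

    def test_ci_transformed_and_reordered(self):
        bx = np.linspace(0.1, 0.3, 4)
        res = ivw(make_hset(bx, 0.01, 0.4 * bx, 0.02))
        scaled = scale_to_unit_decrease(res, 1.0)
        assert scaled.ci_low == pytest.approx(-res.ci_high)
        assert scaled.ci_high == pytest.approx(-res.ci_low)
        assert scaled.ci_low <= scaled.estimate <= scaled.ci_high

    def test_sd_unit_conversion(self):
        res = ivw(make_hset([0.5], [0.01], [0.15], [0.05]))
        scaled = scale_to_unit_decrease(res, 0.5)  # 1 mmol/l = 0.5 exposure SD
        assert scaled.estimate == pytest.approx(-0.5 * res.estimate)

    def test_nonpositive_conversion_rejected(self):
        res = ivw(make_hset([0.5], [0.01], [0.15], [0.05]))
        with pytest.raises(ValueError):
            scale_to_unit_decrease(res, 0.0)
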