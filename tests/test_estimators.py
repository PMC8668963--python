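import numpy as np
import pytest

from mrkit import (
    InsufficientInstrumentsError,
    mr_egger,
    mr_ivw,
    mr_mode,
    mr_weighted_median,
    ratio_estimates,
    run_method,
    to_odds_scale,
)
from mrkit.estimators import METHOD_NAMES
from conftest import make_harmonized


class TestRatioEstimates:
    def test_arithmetic(self):
        h = make_harmonized([0.1], [0.005], [0.02], [0.01])
        r = ratio_estimates(h)
        assert r.theta[0] == pytest.approx(0.2)
        assert r.sigma[0] == pytest.approx(0.1)

    def test_negative_exposure_beta(self):
        h = make_harmonized([-0.1], [0.005], [0.02], [0.01])
        r = ratio_estimates(h)
        assert r.theta[0] == pytest.approx(-0.2)
        assert r.sigma[0] == pytest.approx(0.1)  # SE uses |beta_x|

    def test_zero_exposure_beta_names_snp(self):
        h = make_harmonized([0.1, 0.0], [0.005] * 2, [0.02] * 2, [0.01] * 2)
        with pytest.raises(ValueError, match="rs2"):
            ratio_estimates(h)


class TestIvw:
    def test_closed_form_oracle(self, three_snp_harmonized):
        # frozen from an independent evaluation of sum(w bx by)/sum(w bx^2)
        # with w = se_y^-2: w = (10000, 2500, 4444.44..),
        # numerator = 20 + 25 + 20 = 65, denominator = 100 + 100 + 100 = 300
        est = mr_ivw(three_snp_harmonized)
        assert est.b == pytest.approx(65.0 / 300.0, abs=1e-12)
        assert est.n_snp == 3

    def test_homogeneous_ratios_give_fixed_se(self):
        # all Wald ratios equal c -> b = c, Q = 0, multiplicative floor at 1
        c = 0.4
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, [0.005] * 3, c * bx, [0.01, 0.02, 0.015])
        est = mr_ivw(h)
        assert est.b == pytest.approx(c, abs=1e-12)
        fixed = mr_ivw(h, re_mode="fixed")
        assert est.se == pytest.approx(fixed.se)

    def test_equals_precision_weighted_mean_of_ratios(self, noisy_harmonized):
        r = ratio_estimates(noisy_harmonized)
        w = r.sigma**-2
        expected = float(np.sum(w * r.theta) / np.sum(w))
        assert mr_ivw(noisy_harmonized).b == pytest.approx(expected, abs=1e-12)

    def test_requires_two_instruments(self):
        h = make_harmonized([0.1], [0.005], [0.02], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            mr_ivw(h)

    def test_random_effects_never_narrower_than_fixed(self, noisy_harmonized):
        re = mr_ivw(noisy_harmonized, re_mode="multiplicative_floor")
        fixed = mr_ivw(noisy_harmonized, re_mode="fixed")
        assert re.se >= fixed.se


class TestEgger:
    def test_exact_fit_recovered(self):
        # data on an exact line: alpha0 + b0 * beta_x, no noise
        alpha0, b0 = 0.05, 0.7
        bx = np.array([0.1, 0.15, 0.2, 0.3])
        h = make_harmonized(bx, [0.005] * 4, alpha0 + b0 * bx, [0.01, 0.02, 0.015, 0.01])
        est, pleio = mr_egger(h)
        assert est.b == pytest.approx(b0, abs=1e-10)
        assert pleio.intercept == pytest.approx(alpha0, abs=1e-10)

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.3, 4)
        by = rng.normal(0.02 + 0.5 * bx, 0.01)
        sy = rng.uniform(0.01, 0.03, 4)
        h = make_harmonized(bx, [0.005] * 4, by, sy)
        est, pleio = mr_egger(h)
        # independent route: scaled design matrix + lstsq
        w = np.sqrt(sy**-2.0)
        X = np.column_stack([w, w * bx])
        coef, *_ = np.linalg.lstsq(X, w * by, rcond=None)
        assert pleio.intercept == pytest.approx(coef[0], abs=1e-10)
        assert est.b == pytest.approx(coef[1], abs=1e-10)

    def test_requires_three_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.005] * 2, [0.02, 0.05], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weights_reduce_to_median(self):
        theta = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        bx = np.full(5, 0.1)
        h = make_harmonized(bx, [1e-6] * 5, theta * bx, [0.01] * 5)
        est = mr_weighted_median(h, n_boot=100, seed=0)
        assert est.b == pytest.approx(3.0, abs=1e-9)

    def test_interpolation_hand_instance(self):
        # weights 0.6/0.2/0.2 on theta 1/2/3: cumulative midpoints
        # p = (0.3, 0.7, 0.9); at 0.5 interpolate halfway between 1 and 2
        bx = np.full(3, 0.1)
        theta = np.array([1.0, 2.0, 3.0])
        sy = 0.01 * np.array([np.sqrt(1 / 0.6), np.sqrt(1 / 0.2), np.sqrt(1 / 0.2)])
        h = make_harmonized(bx, [1e-6] * 3, theta * bx, sy)
        est = mr_weighted_median(h, n_boot=100, seed=0)
        assert est.b == pytest.approx(1.5, abs=1e-9)

    def test_rejects_tiny_bootstrap(self, three_snp_harmonized):
        with pytest.raises(ValueError, match="n_boot"):
            mr_weighted_median(three_snp_harmonized, n_boot=10)


class TestMode:
    def test_dominant_cluster(self):
        bx = np.full(4, 0.1)
        theta = np.array([2.0, 2.0, 2.0, 9.0])
        h = make_harmonized(bx, [1e-6] * 4, theta * bx, [0.01] * 4)
        est = mr_mode(h, weighted=False, n_boot=100, seed=0)
        assert est.b == pytest.approx(2.0, abs=0.1)

    def test_weighted_mode_follows_weight_not_count(self):
        # 3 SNPs cluster at theta=1 with tiny weight, 2 SNPs at theta=4 with
        # dominant weight: the weighted mode must sit near 4 (density checked
        # by hand: total weight 0.9 vs 0.1)
        bx = np.full(5, 0.1)
        theta = np.array([1.0, 1.01, 0.99, 4.0, 4.01])
        sy = 0.01 * np.array([3.0, 3.0, 3.0, 0.3, 0.3])
        h = make_harmonized(bx, [1e-6] * 5, theta * bx, sy)
        weighted = mr_mode(h, weighted=True, n_boot=100, seed=0)
        simple = mr_mode(h, weighted=False, n_boot=100, seed=0)
        assert weighted.b == pytest.approx(4.0, abs=0.1)
        assert simple.b == pytest.approx(1.0, abs=0.1)

    def test_degenerate_bandwidth_returns_common_value(self):
        bx = np.full(3, 0.1)
        h = make_harmonized(bx, [1e-6] * 3, 2.0 * bx, [0.01] * 3)
        est = mr_mode(h, weighted=False, n_boot=100, seed=0)
        assert est.b == pytest.approx(2.0, abs=1e-12)


class TestSharedProperties:
    @pytest.mark.parametrize("method", METHOD_NAMES)
    def test_seed_reproducibility(self, noisy_harmonized, method):
        a = run_method(noisy_harmonized, method, n_boot=100, seed=7)
        b = run_method(noisy_harmonized, method, n_boot=100, seed=7)
        assert a.b == b.b and a.se == b.se and a.pval == b.pval

    @pytest.mark.parametrize("method", METHOD_NAMES)
    def test_allele_orientation_equivariance(self, noisy_harmonized, method):
        """Flipping any row's allele orientation (negating beta_x and beta_y)
        leaves every estimator unchanged."""
        flipped = noisy_harmonized.rows.copy()
        rng = np.random.default_rng(1)
        mask = rng.random(len(flipped)) < 0.5
        flipped.loc[mask, ["beta_x", "beta_y"]] *= -1.0
        from mrkit import HarmonizedSet

        h2 = HarmonizedSet("exposure", "outcome", flipped)
        a = run_method(noisy_harmonized, method, n_boot=100, seed=3)
        b = run_method(h2, method, n_boot=100, seed=3)
        assert a.b == pytest.approx(b.b, abs=1e-9)


class TestOddsScale:
    def test_null_effect(self):
        from mrkit import MrEstimate

        e = MrEstimate("ivw", 0.0, 0.1, -0.19599640, 0.19599640, 1.0, 10)
        out = to_odds_scale(e)
        assert out.odds_ratio == pytest.approx(1.0)
        assert out.or_ci_low == pytest.approx(0.822, abs=1e-3)
        assert out.or_ci_high == pytest.approx(1.217, abs=1e-3)

    def test_matches_reported_odds_ratio_scale(self):
        from mrkit import MrEstimate

        b = float(np.log(1.224))
        e = MrEstimate("ivw", b, 0.059, b - 0.1159, b + 0.1159, 5.6e-4, 96)
        assert to_odds_scale(e).odds_ratio == pytest.approx(1.224)

    def test_ci_brackets_or(self, noisy_harmonized):
        est = to_odds_scale(mr_ivw(noisy_harmonized))
        assert est.or_ci_low < est.odds_ratio < est.or_ci_high
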