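"""MR estimators against independent oracles and their symmetries."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrmediate.estimators import (egger, ivw, mode_estimate, p_from_or_ci,
                                  to_or_scale, wald_ratio, weighted_median)

from conftest import make_harmonized


class TestWaldRatio:
    def test_direct_division(self):
        hs = make_harmonized([0.4], [0.2], [0.04])
        est = wald_ratio(hs.pairs.iloc[0])
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_numerator(self):
        est = wald_ratio(make_harmonized([0.4], [0.0], [0.04]).pairs.iloc[0])
        assert est.beta == 0.0 and est.pval == 1.0

    def test_negative_denominator_sign(self):
        est = wald_ratio(make_harmonized([-0.1], [0.05], [0.01]).pairs.iloc[0])
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_instrument_rejected(self):
        with pytest.raises(ValueError, match="null instrument"):
            wald_ratio(make_harmonized([0.0], [0.1], [0.01]).pairs.iloc[0])


class TestIVW:
    def test_constant_ratio_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3])
        hs = make_harmonized(bx, 0.3 * bx, [0.01, 0.02, 0.015])
        est = ivw(hs)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        # zero heterogeneity: random-effects se equals fixed se
        assert est.se == pytest.approx(ivw(hs, model="fixed").se)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_harmonized([0.1], [0.03], [0.01]))

    def test_matches_origin_constrained_wls_oracle(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.05, 0.08, 0.18])
        sy = np.array([0.01, 0.01, 0.02])
        est = ivw(make_harmonized(bx, by, sy), model="fixed")
        # oracle: weighted normal equations solved independently
        w = 1 / sy**2
        beta_oracle = (w * bx * by).sum() / (w * bx * bx).sum()
        assert est.beta == pytest.approx(beta_oracle, abs=1e-12)
        # and against statsmodels WLS through the origin
        fit = sm.WLS(by, bx, weights=w).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hs = make_harmonized(bx, 0.01 + 0.3 * bx, np.full(4, 0.01))
        res = egger(hs)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.01, abs=1e-10)

    def test_collinear_design_rejected(self):
        hs = make_harmonized([0.2, 0.2, 0.2], [0.1, 0.2, 0.3],
                             [0.01, 0.01, 0.01])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            egger(hs)

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            egger(make_harmonized([0.1, 0.2], [0.1, 0.2], [0.01, 0.01]))

    def test_matches_statsmodels_wls_oracle(self, rng):
        bx = rng.uniform(0.05, 0.4, 10)
        by = 0.02 + 0.25 * bx + rng.normal(0, 0.02, 10)
        sy = rng.uniform(0.01, 0.03, 10)
        res = egger(make_harmonized(bx, by, sy))
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-8)
        assert res.slope.beta == pytest.approx(fit.params[1], abs=1e-8)
        # ses match statsmodels under the same multiplicative scale rule
        scale_unclipped = fit.scale
        infl = max(1.0, scale_unclipped) / scale_unclipped
        assert res.slope.se == pytest.approx(
            fit.bse[1] * np.sqrt(infl), rel=1e-6)

    def test_orientation_makes_all_beta_x_positive(self, rng):
        """Sign-flipping a pair's inputs leaves the Egger fit unchanged."""
        bx = rng.uniform(0.05, 0.4, 8)
        by = 0.01 + 0.3 * bx + rng.normal(0, 0.01, 8)
        sy = np.full(8, 0.02)
        res1 = egger(make_harmonized(bx, by, sy))
        flip = np.array([1, -1] * 4)
        res2 = egger(make_harmonized(bx * flip, by * flip, sy))
        assert res2.slope.beta == pytest.approx(res1.slope.beta, abs=1e-12)
        assert res2.intercept == pytest.approx(res1.intercept, abs=1e-12)


class TestWeightedMedian:
    def test_middle_element_equal_weights(self):
        bx = np.ones(3)
        hs = make_harmonized(bx, [0.1, 0.3, 0.5], np.ones(3))
        est = weighted_median(hs, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_dominant_weight_pulls_to_its_ratio(self):
        # one SNP holds ~99% of the inverse-variance weight
        hs = make_harmonized([1, 1, 1], [0.1, 0.3, 0.5],
                             [0.01, 0.099, 0.099])
        est = weighted_median(hs, n_boot=100, seed=1)
        assert abs(est.beta - 0.1) < 0.05

    def test_majority_valid_consistency(self, rng):
        """70% valid instruments at ratio 0.25, 30% shifted: estimate ~ 0.25."""
        m = 40
        bx = rng.uniform(0.1, 0.3, m)
        ratios = np.where(np.arange(m) < 28, 0.25, 1.0)
        sy = np.full(m, 0.002)
        by = ratios * bx + rng.normal(0, sy)
        est = weighted_median(make_harmonized(bx, by, sy), n_boot=200, seed=3)
        assert abs(est.beta - 0.25) < 2 * est.se + 0.02

    def test_seeded_reproducibility_and_order_invariance(self, rng):
        bx = rng.uniform(0.1, 0.3, 9)
        by = 0.3 * bx + rng.normal(0, 0.01, 9)
        sy = rng.uniform(0.01, 0.02, 9)
        a = weighted_median(make_harmonized(bx, by, sy), n_boot=200, seed=11)
        b = weighted_median(make_harmonized(bx, by, sy), n_boot=200, seed=11)
        perm = rng.permutation(9)
        c = weighted_median(make_harmonized(bx[perm], by[perm], sy[perm]),
                            n_boot=200, seed=11)
        assert a.beta == b.beta and a.se == b.se
        assert c.beta == pytest.approx(a.beta, abs=1e-12)


class TestMode:
    def test_identical_ratios(self):
        bx = np.ones(4)
        hs = make_harmonized(bx, 0.3 * bx, np.full(4, 0.01))
        est = mode_estimate(hs, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_simple_mode_tracks_majority_cluster(self):
        bx = np.ones(10)
        by = np.array([0.1] * 7 + [0.6] * 3) + np.linspace(0, 0.01, 10)
        hs = make_harmonized(bx, by, np.full(10, 0.05))
        est = mode_estimate(hs, weighted=False, n_boot=100, seed=1)
        assert abs(est.beta - 0.1) < 0.05

    def test_weighted_mode_tracks_precise_cluster(self):
        bx = np.ones(10)
        by = np.array([0.1] * 7 + [0.6] * 3) + np.linspace(0, 0.01, 10)
        sy = np.array([0.5] * 7 + [0.001] * 3)  # weight on the 0.6 cluster
        est = mode_estimate(make_harmonized(bx, by, sy), weighted=True,
                            n_boot=100, seed=1)
        assert abs(est.beta - 0.6) < 0.05


class TestORScale:
    def test_null_beta(self):
        or_, lo, hi, p = to_or_scale(0.0, 0.1)
        assert or_ == 1.0 and p == 1.0

    def test_log_or_round_trip(self):
        or_, *_ = to_or_scale(np.log(2.121), 0.1)
        assert or_ == pytest.approx(2.121)

    def test_published_style_interval(self):
        # beta -0.284, se 0.1387 -> OR ~0.753, CI ~(0.573, 0.988), p ~0.040
        or_, lo, hi, p = to_or_scale(-0.284, 0.1387)
        assert or_ == pytest.approx(0.753, abs=5e-4)
        assert lo == pytest.approx(0.573, abs=2e-3)
        assert hi == pytest.approx(0.988, abs=2e-3)
        assert p == pytest.approx(0.0406, abs=5e-4)

    def test_p_from_or_ci_symmetric_null(self):
        assert p_from_or_ci(1.0, 0.5, 2.0) == pytest.approx(1.0)

    def test_p_from_or_ci_ordering_enforced(self):
        with pytest.raises(ValueError):
            p_from_or_ci(0.5, 0.6, 0.7)


class TestSymmetries:
    @given(seed=st.integers(0, 1000))
    @settings(max_examples=15, deadline=None)
    def test_sign_equivariance(self, seed):
        """Negating every beta_y negates each estimate, se unchanged."""
        r = np.random.default_rng(seed)
        bx = r.uniform(0.05, 0.4, 8)
        by = 0.3 * bx + r.normal(0, 0.02, 8)
        sy = r.uniform(0.01, 0.03, 8)
        for fit, exact_se in ((lambda h: ivw(h), True),
                              (lambda h: egger(h).slope, True),
                              (lambda h: weighted_median(
                                  h, n_boot=100, seed=5), False)):
            a = fit(make_harmonized(bx, by, sy))
            b = fit(make_harmonized(bx, -by, sy))
            assert b.beta == pytest.approx(-a.beta, abs=1e-10)
            if exact_se:  # bootstrap ses are only distributionally equal
                assert b.se == pytest.approx(a.se, rel=1e-9)

    @given(c=st.floats(0.1, 10))
    @settings(max_examples=15, deadline=None)
    def test_scale_equivariance(self, c):
        """Multiplying all beta_x by c divides each estimate by c."""
        r = np.random.default_rng(3)
        bx = r.uniform(0.05, 0.4, 8)
        by = 0.3 * bx + r.normal(0, 0.02, 8)
        sy = r.uniform(0.01, 0.03, 8)
        a = ivw(make_harmonized(bx, by, sy))
        b = ivw(make_harmonized(c * bx, by, sy))
        assert b.beta == pytest.approx(a.beta / c, rel=1e-9)

    def test_two_identical_pairs_match_wald_ratio(self):
        hs2 = make_harmonized([0.2, 0.2], [0.06, 0.06], [0.01, 0.01])
        pair = make_harmonized([0.2], [0.06], [0.01]).pairs.iloc[0]
        assert ivw(hs2).beta == pytest.approx(wald_ratio(pair).beta)
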