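"""Heterogeneity/pleiotropy diagnostics: closed forms, null behavior, power."""

import numpy as np
import pytest
from scipy import stats

from mrmediate.estimators import ivw
from mrmediate.sensitivity import (cochran_q, egger_intercept_test,
                                   leave_one_out, mr_presso,
                                   sensitivity_report)

from conftest import make_harmonized


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        q, df, p = cochran_q(make_harmonized(bx, 0.3 * bx, np.full(3, 0.01)))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_two_term_closed_form(self):
        # equal weights w: Q = w (r1 - rbar)^2 + w (r2 - rbar)^2
        bx = np.array([1.0, 1.0])
        by = np.array([0.0, 1.0])
        sy = np.array([0.5, 0.5])
        q, df, _ = cochran_q(make_harmonized(bx, by, sy))
        w = 1 / 0.25
        rbar = 0.5
        assert q == pytest.approx(w * 0.25 + w * 0.25)
        assert df == 1

    def test_invariant_to_order_and_joint_sign_flip(self, rng):
        bx = rng.uniform(0.1, 0.4, 8)
        by = 0.3 * bx + rng.normal(0, 0.02, 8)
        sy = rng.uniform(0.01, 0.03, 8)
        q0, *_ = cochran_q(make_harmonized(bx, by, sy))
        perm = rng.permutation(8)
        q1, *_ = cochran_q(make_harmonized(bx[perm], by[perm], sy[perm]))
        q2, *_ = cochran_q(make_harmonized(-bx, -by, sy))
        assert q1 == pytest.approx(q0, rel=1e-12)
        assert q2 == pytest.approx(q0, rel=1e-12)

    def test_null_pvalues_uniform(self, rng):
        """Homogeneous sets: Q p-values are Uniform(0,1) (KS check)."""
        m, reps = 10, 400
        pvals = np.empty(reps)
        for i in range(reps):
            bx = rng.uniform(0.1, 0.4, m)
            sy = rng.uniform(0.01, 0.03, m)
            by = 0.3 * bx + rng.normal(0, sy)
            _, _, pvals[i] = cochran_q(make_harmonized(bx, by, sy))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestEggerIntercept:
    def test_exact_zero_intercept_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inter, se, p = egger_intercept_test(
            make_harmonized(bx, 0.3 * bx, np.full(4, 0.01)))
        assert inter == pytest.approx(0.0, abs=1e-10)

    def test_balanced_pleiotropy_coverage(self, rng):
        """Mean-zero pleiotropy: intercept within 2 se of 0 in >= 93% of reps."""
        reps, m = 300, 30
        cover = 0
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.4, m)
            sy = np.full(m, 0.02)
            alpha = rng.normal(0, 0.02, m)
            by = 0.3 * bx + alpha + rng.normal(0, sy)
            inter, se, _ = egger_intercept_test(make_harmonized(bx, by, sy))
            cover += abs(inter) <= 2 * se
        assert cover / reps >= 0.93

    def test_directional_pleiotropy_recovered(self, rng):
        """A planted +0.02 mean pleiotropic effect is recovered on average."""
        reps, m = 200, 50
        est = np.empty(reps)
        for i in range(reps):
            bx = rng.uniform(0.1, 0.5, m)
            sy = np.full(m, 0.01)
            by = 0.02 + 0.3 * bx + rng.normal(0, sy)
            est[i], *_ = egger_intercept_test(make_harmonized(bx, by, sy))
        assert 0.015 <= est.mean() <= 0.025


class TestPresso:
    def _homogeneous(self, rng, m=10):
        bx = rng.uniform(0.1, 0.4, m)
        sy = rng.uniform(0.01, 0.03, m)
        by = 0.3 * bx + rng.normal(0, sy)
        return make_harmonized(bx, by, sy)

    def test_determinism_under_seed(self, rng):
        hs = self._homogeneous(rng)
        p1, o1 = mr_presso(hs, n_sim=100, seed=42)
        p2, o2 = mr_presso(hs, n_sim=100, seed=42)
        assert p1 == p2 and o1 == o2

    def test_global_p_bounds(self, rng):
        hs = self._homogeneous(rng)
        p, _ = mr_presso(hs, n_sim=100, seed=0)
        assert 1 / 101 <= p <= 1.0

    def test_minimum_instruments(self):
        hs = make_harmonized([0.1, 0.2, 0.3], [0.03, 0.06, 0.09],
                             [0.01, 0.01, 0.01])
        with pytest.raises(ValueError, match="insufficient"):
            mr_presso(hs, n_sim=100, seed=0)

    def test_null_rarely_significant(self, rng):
        hits = sum(mr_presso(self._homogeneous(rng), n_sim=200,
                             seed=i)[0] <= 0.05 for i in range(100))
        assert hits / 100 <= 0.10

    def test_gross_outlier_flagged(self, rng):
        """A SNP with 5x the common ratio and tiny se is flagged."""
        flagged = 0
        reps = 100
        for i in range(reps):
            bx = rng.uniform(0.2, 0.4, 10)
            sy = np.full(10, 0.005)
            by = 0.3 * bx + rng.normal(0, sy)
            by[0] = 1.5 * bx[0]  # ratio 1.5 vs 0.3
            hs = make_harmonized(bx, by, sy)
            _, outliers = mr_presso(hs, n_sim=200, seed=i)
            flagged += "rs0" in outliers
        assert flagged / reps >= 0.90

    def test_outlier_removal_never_increases_q(self, rng):
        for i in range(20):
            bx = rng.uniform(0.1, 0.4, 12)
            sy = np.full(12, 0.01)
            by = 0.3 * bx + rng.normal(0, 3 * sy)  # overdispersed
            hs = make_harmonized(bx, by, sy)
            q_full, *_ = cochran_q(hs)
            _, outliers = mr_presso(hs, n_sim=200, seed=i)
            if 0 < len(outliers) <= 10:
                keep = ~hs.pairs["snp"].isin(outliers).to_numpy()
                hs2 = make_harmonized(bx[keep], by[keep], sy[keep])
                q_red, *_ = cochran_q(hs2)
                assert q_red <= q_full + 1e-9


class TestLeaveOneOut:
    def test_rows_equal_complement_ivw(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.04, 0.05, 0.10])
        sy = np.array([0.01, 0.02, 0.01])
        loo = leave_one_out(make_harmonized(bx, by, sy))
        assert len(loo) == 3
        for j in range(3):
            keep = np.arange(3) != j
            expected = ivw(make_harmonized(bx[keep], by[keep], sy[keep]))
            assert loo["beta"].iloc[j] == pytest.approx(expected.beta)
            assert loo["se"].iloc[j] == pytest.approx(expected.se)

    def test_homogeneous_stability(self, rng):
        bx = rng.uniform(0.1, 0.4, 12)
        sy = np.full(12, 0.02)
        by = 0.3 * bx + rng.normal(0, sy)
        hs = make_harmonized(bx, by, sy)
        full = ivw(hs)
        loo = leave_one_out(hs)
        assert (np.abs(loo["beta"] - full.beta) <= full.se + 1e-12).all()

    def test_outlier_row_moves_most(self, rng):
        bx = rng.uniform(0.2, 0.4, 8)
        sy = np.full(8, 0.01)
        by = 0.3 * bx + rng.normal(0, sy)
        by[3] = 2.0 * bx[3]
        hs = make_harmonized(bx, by, sy)
        full = ivw(hs, model="fixed")
        loo = leave_one_out(hs, model="fixed")
        shifts = np.abs(loo["beta"] - full.beta)
        assert shifts.idxmax() == 3


def test_report_assembles_available_diagnostics(rng):
    bx = rng.uniform(0.1, 0.4, 6)
    sy = np.full(6, 0.02)
    by = 0.3 * bx + rng.normal(0, sy)
    rep = sensitivity_report(make_harmonized(bx, by, sy), n_sim=100, seed=1)
    assert rep.q_df == 5
    assert rep.egger_intercept_p is not None
    assert rep.presso_global_p is not None
    assert len(rep.loo) == 6
    d = rep.to_dict()
    assert set(d) >= {"q_stat", "q_pval", "presso_global_p", "loo"}
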