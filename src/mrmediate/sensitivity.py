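"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
fixed-effect IVW pool; the MR-Egger intercept tests for directional
pleiotropy; MR-PRESSO compares the observed leave-one-out residual sum of
squares against its Monte-Carlo distribution under the fitted model and
flags per-SNP outliers; leave-one-out re-estimates IVW dropping each SNP
in turn to expose single-variant influence.

The MR-PRESSO distortion test is not implemented; the global and outlier
tests are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import _egger_arrays, _ivw_arrays, _make_estimate, _two_sided_p
from .harmonize import HarmonizedSet


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    presso_global_p: float | None
    presso_outliers: list[str] = field(default_factory=list)
    loo: pd.DataFrame | None = None
    ivw_model: str = "multiplicative_random"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("q_stat", "q_df", "q_pval", "egger_intercept",
              "egger_intercept_se", "egger_intercept_p", "presso_global_p",
              "presso_outliers", "ivw_model")}
        if self.loo is not None:
            d["loo"] = self.loo.to_dict(orient="records")
        return d


def cochran_q(hs: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q of the Wald ratios against the fixed-effect IVW pool.

    Q = Σ w_j (r_j − β̂)² with w_j = β_xj²/se_yj²; chi-square with m−1 df.
    """
    bx, _, by, sy = hs.arrays()
    m = len(bx)
    if m < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    _, _, q = _ivw_arrays(bx, by, sy, "fixed")
    df = m - 1
    return float(q), df, float(stats.chi2.sf(q, df))


def egger_intercept_test(hs: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, two-sided p) from the MR-Egger regression."""
    bx, _, by, sy = hs.arrays()
    if len(bx) < 3:
        raise ValueError("Egger intercept test requires at least 3 instruments")
    _, _, inter, inter_se, _ = _egger_arrays(bx, by, sy)
    return inter, inter_se, _two_sided_p(inter / inter_se)


def mr_presso(hs: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> tuple[float, list[str]]:
    """MR-PRESSO global test and outlier detection.

    The observed residual sum of squares uses, for each SNP j, the IVW
    slope fitted without j:  RSS = Σ_j w_j (β_yj − β̂₍₋ⱼ₎ β_xj)² with
    w_j = 1/se_yj².  ``n_sim`` replicates redraw β_yj* ~ N(β̂₍₋ⱼ₎ β_xj,
    se_yj) and recompute RSS the same way; the global p is the rank-based
    (1 + #{RSS* ≥ RSS}) / (n_sim + 1).  A SNP is an outlier when its
    observed RSS term exceeds the 1 − outlier_alpha/m quantile of its
    simulated terms (Bonferroni-style per-SNP level).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    kept = hs.kept()
    bx, by, sy = (kept["beta_x"].to_numpy(), kept["beta_y"].to_numpy(),
                  kept["se_y"].to_numpy())
    m = len(bx)
    if m < 4:
        raise ValueError("insufficient instruments for PRESSO (need >= 4)")
    w = 1.0 / sy ** 2
    s_xy = float(np.sum(w * bx * by))
    s_xx = float(np.sum(w * bx * bx))
    loo_slope = (s_xy - w * bx * by) / (s_xx - w * bx * bx)
    expected = loo_slope * bx
    t_obs = w * (by - expected) ** 2
    rss_obs = float(t_obs.sum())

    rng = np.random.default_rng(seed)
    y_sim = expected[None, :] + rng.standard_normal((n_sim, m)) * sy[None, :]
    s_xy_sim = (w * bx * y_sim).sum(axis=1, keepdims=True)
    loo_sim = (s_xy_sim - w * bx * y_sim) / (s_xx - w * bx * bx)
    t_sim = w * (y_sim - loo_sim * bx) ** 2
    rss_sim = t_sim.sum(axis=1)

    global_p = (1 + int((rss_sim >= rss_obs).sum())) / (n_sim + 1)
    thresh = np.quantile(t_sim, 1.0 - outlier_alpha / m, axis=0)
    outliers = list(kept["snp"][t_obs > thresh])
    return float(global_p), outliers


def leave_one_out(hs: HarmonizedSet, model: str = "multiplicative_random",
                  ) -> pd.DataFrame:
    """One IVW estimate per left-out SNP; columns snp, beta, se, pval."""
    kept = hs.kept()
    bx, by, sy = (kept["beta_x"].to_numpy(), kept["beta_y"].to_numpy(),
                  kept["se_y"].to_numpy())
    m = len(bx)
    if m < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    rows = []
    for j in range(m):
        keep = np.arange(m) != j
        beta, se, _ = _ivw_arrays(bx[keep], by[keep], sy[keep], model)
        est = _make_estimate("ivw", beta, se, m - 1)
        rows.append(dict(snp=kept["snp"].iloc[j], beta=est.beta, se=est.se,
                         pval=est.pval))
    return pd.DataFrame(rows)


def sensitivity_report(hs: HarmonizedSet, n_sim: int = 1000,
                       seed: int | None = None, outlier_alpha: float = 0.05,
                       ivw_model: str = "multiplicative_random",
                       ) -> SensitivityReport:
    """All diagnostics that the instrument count permits.

    Q needs m ≥ 2, Egger and leave-one-out m ≥ 3, PRESSO m ≥ 4; diagnostics
    below their minimum are reported as None/empty.
    """
    q, df, qp = cochran_q(hs)
    rep = SensitivityReport(q_stat=q, q_df=df, q_pval=qp,
                            egger_intercept=None, egger_intercept_se=None,
                            egger_intercept_p=None, presso_global_p=None,
                            ivw_model=ivw_model)
    if hs.n_kept >= 3:
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_p = (
            egger_intercept_test(hs))
        rep.loo = leave_one_out(hs, model=ivw_model)
    if hs.n_kept >= 4:
        rep.presso_global_p, rep.presso_outliers = mr_presso(
            hs, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
    return rep
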