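"""Two-step MR mediation: product of coefficients with delta-method CIs.

The total causal effect of an exposure X on an outcome Y is decomposed via
a mediator M into an indirect path and a direct remainder:

* step 1 — IVW of X's instruments on M gives β₁ (exposure → mediator);
* step 2 — IVW of M's instruments on Y gives β₂ (mediator → outcome),
  after removing from M's instrument set any SNP significantly associated
  with X, so the two steps use independent instruments;
* the indirect effect is β₁β₂ with the first-order delta (Sobel) standard
  error √(β₁²se₂² + β₂²se₁²);
* the mediated proportion is β₁β₂ / β_total, where β_total is the IVW of X
  on Y.

The proportion CI divides the indirect-effect CI endpoints by β_total
(total effect treated as fixed), re-ordering the endpoints when β_total is
negative; a two-term delta variant that also propagates se_total is
available via ``proportion_ci="delta"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import Z95, ivw
from .harmonize import harmonize
from .instruments import InstrumentSet, SelectionConfig, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import SummaryStats


@dataclass
class MediationResult:
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_total: float
    se_total: float
    indirect: float
    indirect_se: float
    indirect_ci_low: float
    indirect_ci_high: float
    proportion: float
    proportion_ci_low: float
    proportion_ci_high: float
    n_excluded_snps: int
    nsnp_step1: int = 0
    nsnp_step2: int = 0
    nsnp_total: int = 0
    reports: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("beta1", "se1", "beta2", "se2", "beta_total", "se_total",
                 "indirect", "indirect_se", "indirect_ci_low",
                 "indirect_ci_high", "proportion", "proportion_ci_low",
                 "proportion_ci_high", "n_excluded_snps", "nsnp_step1",
                 "nsnp_step2", "nsnp_total")}


def exclude_overlapping_instruments(mediator_instruments: InstrumentSet,
                                    exposure_ss: SummaryStats,
                                    p_overlap: float = 5e-6) -> InstrumentSet:
    """Drop mediator instruments significantly associated with the exposure.

    A SNP is removed when its p-value in ``exposure_ss`` is strictly below
    ``p_overlap``; SNPs absent from the exposure table are retained.  The
    returned set carries ``n_excluded_snps``.
    """
    if len(mediator_instruments) == 0 or len(exposure_ss) == 0:
        raise ValueError("empty input")

    def independent(sid: str) -> bool:
        return not (sid in exposure_ss
                    and exposure_ss.get(sid)["pval"] < p_overlap)

    mask = mediator_instruments.records["snp"].map(independent)
    kept = mediator_instruments.records[mask].reset_index(drop=True)
    n_excluded = len(mediator_instruments) - len(kept)
    if kept.empty:
        raise ValueError("no independent mediator instruments")
    out = InstrumentSet(mediator_instruments.exposure_trait_id, kept,
                        mediator_instruments.config)
    out.n_excluded_snps = n_excluded  # type: ignore[attr-defined]
    return out


def indirect_effect(beta1: float, se1: float, beta2: float, se2: float,
                    ) -> tuple[float, float, tuple[float, float]]:
    """Product-of-coefficients indirect effect with Sobel se and 95% CI."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    indirect = beta1 * beta2
    se = float(np.sqrt(beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2))
    return indirect, se, (indirect - Z95 * se, indirect + Z95 * se)


def mediated_proportion(indirect: float, indirect_se: float,
                        beta_total: float, se_total: float = 0.0,
                        method: str = "fixed_total",
                        ) -> tuple[float, tuple[float, float]]:
    """Share of the total effect flowing through the mediator.

    ``fixed_total`` (default) divides the indirect CI endpoints by
    β_total, re-ordering when β_total < 0; ``delta`` propagates se_total
    with the ratio delta-method variance.
    """
    if beta_total == 0:
        raise ValueError("undefined proportion: beta_total = 0")
    prop = indirect / beta_total
    if method == "fixed_total":
        lo = (indirect - Z95 * indirect_se) / beta_total
        hi = (indirect + Z95 * indirect_se) / beta_total
        if lo > hi:
            lo, hi = hi, lo
    elif method == "delta":
        var = (indirect_se ** 2 / beta_total ** 2
               + indirect ** 2 * se_total ** 2 / beta_total ** 4)
        half = Z95 * float(np.sqrt(var))
        lo, hi = prop - half, prop + half
    else:
        raise ValueError(f"unknown proportion CI method: {method!r}")
    return float(prop), (float(lo), float(hi))


def run_mediation(exposure: SummaryStats, mediator: SummaryStats,
                  outcome: SummaryStats,
                  config: SelectionConfig | None = None,
                  seed: int | None = None,
                  ivw_model: str = "multiplicative_random",
                  p_overlap: float | None = None,
                  proportion_ci: str = "fixed_total",
                  with_sensitivity: bool = True,
                  presso_n_sim: int = 1000) -> MediationResult:
    """Full two-step mediation analysis on three summary-stat tables.

    All three component IVW fits use the same ``ivw_model`` so the product
    and ratio stay interpretable.  ``p_overlap`` defaults to the
    instrument-selection threshold.  When ``with_sensitivity`` each step
    also gets a full :class:`SensitivityReport` under ``result.reports``.
    """
    config = config or SelectionConfig()
    if p_overlap is None:
        p_overlap = config.p_threshold

    def _step(label, exp_ss, out_ss, inst):
        if len(inst) == 0:
            raise ValueError(f"{label}: no instruments for {exp_ss.trait_id}")
        try:
            hs = harmonize(exp_ss, out_ss, inst.snp_ids)
            est = ivw(hs, model=ivw_model)
        except ValueError as err:
            raise ValueError(f"{label}: {err}") from err
        return hs, est

    x_inst = select_instruments(exposure, config)
    m_inst = select_instruments(mediator, config)
    m_inst_indep = exclude_overlapping_instruments(m_inst, exposure, p_overlap)

    hs1, est1 = _step("step1 (exposure->mediator)", exposure, mediator, x_inst)
    hs2, est2 = _step("step2 (mediator->outcome)", mediator, outcome,
                      m_inst_indep)
    hs_t, est_t = _step("total (exposure->outcome)", exposure, outcome, x_inst)

    indirect, ind_se, (ind_lo, ind_hi) = indirect_effect(
        est1.beta, est1.se, est2.beta, est2.se)
    prop, (p_lo, p_hi) = mediated_proportion(
        indirect, ind_se, est_t.beta, est_t.se, method=proportion_ci)

    reports: dict[str, SensitivityReport] = {}
    if with_sensitivity:
        for label, hs in (("step1", hs1), ("step2", hs2), ("total", hs_t)):
            if hs.n_kept >= 2:
                reports[label] = sensitivity_report(
                    hs, n_sim=presso_n_sim, seed=seed, ivw_model=ivw_model)

    return MediationResult(
        beta1=est1.beta, se1=est1.se, beta2=est2.beta, se2=est2.se,
        beta_total=est_t.beta, se_total=est_t.se,
        indirect=indirect, indirect_se=ind_se,
        indirect_ci_low=ind_lo, indirect_ci_high=ind_hi,
        proportion=prop, proportion_ci_low=p_lo, proportion_ci_high=p_hi,
        n_excluded_snps=getattr(m_inst_indep, "n_excluded_snps", 0),
        nsnp_step1=est1.nsnp, nsnp_step2=est2.nsnp, nsnp_total=est_t.nsnp,
        reports=reports,
    )
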