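"""Synthetic GWAS summary statistics under a known three-trait causal model.

The generator emulates the shape of a two-sample MR study with mediation:
an exposure X (micronutrient-scale GWAS), a mediator M (blood-metabolite
GWAS), and an outcome Y (large case-control GWAS on the log-odds scale),
linked by the linear structural model

    M = θ_xm · X + ε_M,      Y = θ_direct · X + θ_my · M + ε_Y,

so the total effect of X on Y is θ_direct + θ_xm·θ_my and the indirect
(mediated) effect is θ_xm·θ_my.  Instruments are simulated at the
summary-statistic level: per-SNP true effects are drawn and rescaled to a
target variance explained, then observed betas add independent sampling
noise with se = 1/√(2·maf(1−maf)·n) (standardized-trait approximation),
independently per trait — a no-sample-overlap two-sample design.

Allele metadata deliberately stresses harmonization: about 8% of SNPs are
palindromic (A/T or G/C) and about 20% of outcome rows are reported on the
opposite strand.  Positions are spaced farther apart than the default clump
window, so clumping is the identity unless linkage is planted explicitly.

Default parameter scale mirrors a micronutrient/metabolite/disk-
degeneration study: m = 9 exposure instruments, n_x = 64,979,
n_m = 8,299, n_y = 184,683 (≈ 20,001 cases + 164,682 controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStats, TraitMeta, TINY_P

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the three-trait model.

    ``var_explained_x`` (``_m``) is the total exposure (mediator-specific)
    variance explained by the m (m_med) instruments; ``pleiotropy_mean``/
    ``_sd`` give each SNP a direct effect on the outcome bypassing both
    X and M (horizontal pleiotropy).
    """

    m: int = 9
    m_med: int = 15
    maf_range: tuple[float, float] = (0.05, 0.5)
    var_explained_x: float = 0.02
    var_explained_m: float = 0.05
    theta_xm: float = 0.5
    theta_my: float = -0.1
    theta_direct: float = -0.25
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_x: int = 64_979
    n_m: int = 8_299
    n_y: int = 184_683
    palindromic_frac: float = 0.08
    strand_flip_frac: float = 0.20
    position_spacing_kb: float = 20_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.m_med < 0:
            raise ValueError("m_med must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be ordered within (0, 0.5]")
        for name in ("n_x", "n_m", "n_y"):
            if getattr(self, name) <= 2:
                raise ValueError(f"{name} must be > 2")
        if not 0 < self.var_explained_x < 1:
            raise ValueError("var_explained_x must be in (0,1)")
        if not 0 < self.var_explained_m < 1:
            raise ValueError("var_explained_m must be in (0,1)")


@dataclass
class TruthTable:
    """Generative truth every estimator is measured against."""

    beta1_true: float
    beta2_true: float
    total_true: float
    indirect_true: float
    proportion_true: float
    per_snp: pd.DataFrame  # snp, b_x, b_m, b_y true effects

    def summary(self) -> pd.DataFrame:
        """The five headline truth values as a printable table."""
        return pd.DataFrame(
            {"quantity": ["beta1_true", "beta2_true", "total_true",
                          "indirect_true", "proportion_true"],
             "value": [self.beta1_true, self.beta2_true, self.total_true,
                       self.indirect_true, self.proportion_true]})


def truth_summary(truth: TruthTable) -> pd.DataFrame:
    return truth.summary()


def _scaled_effects(rng, maf: np.ndarray, total_var: float) -> np.ndarray:
    """Per-SNP effects rescaled so Σ 2·maf(1−maf)·b² = total_var.

    Magnitudes are uniform in [0.5, 1.5] (sign random) before rescaling, so
    every planted SNP contributes a comparable share of the variance and is
    a genuine instrument — none is left below its own significance filter.
    """
    b = rng.choice([-1.0, 1.0], maf.size) * rng.uniform(0.5, 1.5, maf.size)
    var = float(np.sum(2 * maf * (1 - maf) * b ** 2))
    return b * np.sqrt(total_var / var)


def _observed_table(rng, snp, chrom, pos, ea, oa, maf, true_beta, n,
                    meta: TraitMeta) -> SummaryStats:
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
    beta = true_beta + rng.standard_normal(maf.size) * se
    pval = np.maximum(2 * stats.norm.sf(np.abs(beta / se)), TINY_P)
    df = pd.DataFrame({
        "snp": snp, "chr": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "eaf": maf, "beta": beta, "se": se, "pval": pval,
        "n": float(n),
    })
    return SummaryStats(meta, df)


def simulate_sumstats(config: SimulationConfig | None = None,
                      ) -> tuple[SummaryStats, SummaryStats, SummaryStats,
                                 TruthTable]:
    """Generate (exposure, mediator, outcome, truth) for one seed.

    The three tables share SNP ids and alleles (up to the planted strand
    flips in the outcome).  Byte-identical across calls at a fixed config.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    m_tot = config.m + config.m_med

    snp = np.array([f"rs{j + 1:06d}" for j in range(m_tot)])
    chrom = np.array([str(j % 22 + 1) for j in range(m_tot)])
    pos = np.array([(j // 22 + 1) * config.position_spacing_kb * 1000 + 1
                    for j in range(m_tot)], dtype=float)
    maf = rng.uniform(*config.maf_range, size=m_tot)

    is_pal = rng.random(m_tot) < config.palindromic_frac
    pairs = np.empty((m_tot, 2), dtype=object)
    pal_choices = rng.integers(0, len(_PALINDROMIC), size=m_tot)
    non_choices = rng.integers(0, len(_NONPALINDROMIC), size=m_tot)
    for j in range(m_tot):
        pairs[j] = (_PALINDROMIC[pal_choices[j]] if is_pal[j]
                    else _NONPALINDROMIC[non_choices[j]])
    ea, oa = pairs[:, 0].astype(str), pairs[:, 1].astype(str)

    b_x = np.zeros(m_tot)
    b_x[:config.m] = _scaled_effects(rng, maf[:config.m],
                                     config.var_explained_x)
    b_m_own = np.zeros(m_tot)
    if config.m_med:
        b_m_own[config.m:] = _scaled_effects(rng, maf[config.m:],
                                             config.var_explained_m)
    b_m = config.theta_xm * b_x + b_m_own
    alpha = (rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, m_tot)
             if config.pleiotropy_sd > 0
             else np.full(m_tot, config.pleiotropy_mean))
    b_y = config.theta_direct * b_x + config.theta_my * b_m + alpha

    exposure = _observed_table(
        rng, snp, chrom, pos, ea, oa, maf, b_x, config.n_x,
        TraitMeta("sim-exposure", "simulated exposure"))
    mediator = _observed_table(
        rng, snp, chrom, pos, ea, oa, maf, b_m, config.n_m,
        TraitMeta("sim-mediator", "simulated mediator"))
    outcome = _observed_table(
        rng, snp, chrom, pos, ea, oa, maf, b_y, config.n_y,
        TraitMeta("sim-outcome", "simulated outcome", trait_type="binary"))

    # report ~20% of outcome rows on the opposite strand (pure renaming;
    # harmonization must undo it exactly)
    flip = rng.random(m_tot) < config.strand_flip_frac
    out_df = outcome.records
    out_df.loc[flip, "effect_allele"] = [
        _COMP[a] for a in out_df.loc[flip, "effect_allele"]]
    out_df.loc[flip, "other_allele"] = [
        _COMP[a] for a in out_df.loc[flip, "other_allele"]]

    total_true = config.theta_direct + config.theta_xm * config.theta_my
    indirect_true = config.theta_xm * config.theta_my
    truth = TruthTable(
        beta1_true=config.theta_xm, beta2_true=config.theta_my,
        total_true=total_true, indirect_true=indirect_true,
        proportion_true=indirect_true / total_true if total_true else np.nan,
        per_snp=pd.DataFrame({"snp": snp, "b_x": b_x, "b_m": b_m, "b_y": b_y}),
    )
    return exposure, mediator, outcome, truth


def simulate_null_exposures(n_traits: int, outcome_config: SimulationConfig,
                            seed: int) -> tuple[list[SummaryStats],
                                                SummaryStats]:
    """A battery of exposures with instruments but no effect on the outcome.

    Each exposure gets its own SNP panel and the shared outcome table holds
    pure-noise associations at those SNPs (θ = 0 everywhere), the null of a
    multi-trait screen.
    """
    rng = np.random.default_rng(seed)
    exposures = []
    out_frames = []
    for t in range(n_traits):
        cfg = SimulationConfig(
            m=outcome_config.m, m_med=0,
            maf_range=outcome_config.maf_range,
            var_explained_x=outcome_config.var_explained_x,
            theta_xm=0.0, theta_my=0.0, theta_direct=0.0,
            n_x=outcome_config.n_x, n_m=outcome_config.n_m,
            n_y=outcome_config.n_y,
            palindromic_frac=outcome_config.palindromic_frac,
            strand_flip_frac=outcome_config.strand_flip_frac,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        exp, _, out, _ = simulate_sumstats(cfg)
        prefix = f"t{t:03d}_"
        for ss in (exp, out):
            ss.records["snp"] = prefix + ss.records["snp"]
        exposures.append(SummaryStats(
            TraitMeta(f"sim-null-{t:03d}", f"null exposure {t}"),
            exp.records))
        out_frames.append(out.records)
    outcome = SummaryStats(
        TraitMeta("sim-outcome", "simulated outcome", trait_type="binary"),
        pd.concat(out_frames, ignore_index=True))
    return exposures, outcome
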