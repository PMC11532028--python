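import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrmediate.harmonize import HarmonizedSet
from mrmediate.sumstats import SummaryStats, TraitMeta

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def make_sumstats(rows, trait_id="trait", trait_type="continuous"):
    """SummaryStats from a list of dicts with canonical fields."""
    defaults = dict(chr="1", pos=1, eaf=np.nan, n=10_000.0)
    full = [{**defaults, **r} for r in rows]
    df = pd.DataFrame(full)[["snp", "chr", "pos", "effect_allele",
                             "other_allele", "eaf", "beta", "se", "pval", "n"]]
    return SummaryStats(TraitMeta(trait_id, trait_type=trait_type), df)


def make_harmonized(beta_x, beta_y, se_y, se_x=None, snp=None,
                    exposure="X", outcome="Y"):
    """HarmonizedSet built directly from effect arrays (all pairs kept)."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    se_x = (np.zeros_like(beta_x) if se_x is None
            else np.asarray(se_x, dtype=float))
    m = beta_x.size
    snp = snp if snp is not None else [f"rs{j}" for j in range(m)]
    pairs = pd.DataFrame({
        "snp": snp, "beta_x": beta_x, "se_x": se_x, "beta_y": beta_y,
        "se_y": se_y, "eaf_x": np.nan, "eaf_y": np.nan,
        "action": "kept", "reason": "",
    })
    return HarmonizedSet(pairs, exposure, outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_sumstats():
    return make_sumstats([
        dict(snp="rs1", pos=1_000, effect_allele="A", other_allele="G",
             eaf=0.3, beta=0.10, se=0.01, pval=1e-20),
        dict(snp="rs2", chr="2", pos=2_000, effect_allele="C",
             other_allele="T", eaf=0.2, beta=-0.08, se=0.012, pval=1e-12),
        dict(snp="rs3", chr="3", pos=3_000, effect_allele="G",
             other_allele="A", eaf=0.45, beta=0.05, se=0.013558, pval=2e-8),
        dict(snp="rs4", chr="4", pos=4_000, effect_allele="T",
             other_allele="C", eaf=0.1, beta=0.12, se=0.02, pval=3e-9),
        dict(snp="rs5", chr="5", pos=5_000, effect_allele="A",
             other_allele="C", eaf=0.25, beta=0.07, se=0.011, pval=4e-10),
    ])
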