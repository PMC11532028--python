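"""Genetic-instrument selection: significance filter, clumping, R², F.

An instrument must (1) reach the significance threshold in the exposure
GWAS, (2) be approximately independent of the other instruments — enforced
by greedy clumping on distance and, when an LD matrix is supplied, on
squared correlation — and (3) be strong, conventionally F > 10 with

    F = R² (n − 2) / (1 − R²),

where R² is the phenotypic variance the variant explains.  R² can be
computed from allele frequency and effect size, 2·eaf·(1−eaf)·β² (valid for
a standardized continuous trait), or frequency-free from the z-statistic,
z²/(z² + n − 2).  With the z-based R², F reduces algebraically to z².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd

from .sumstats import SummaryStats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Instrument-selection thresholds.

    Defaults: p < 5e-6, clump window 10,000 kb, LD r² < 0.001, F > 10.
    """

    p_threshold: float = 5e-6
    clump_window_kb: float = 10_000.0
    r2_threshold: float = 0.001
    f_min: float = 10.0
    r2_method: str = "z_n"  # {z_n, eaf_beta}

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be > 0")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0,1]")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")
        if self.r2_method not in ("z_n", "eaf_beta"):
            raise ValueError(f"unknown r2_method: {self.r2_method!r}")


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with per-SNP R² and F."""

    exposure_trait_id: str
    records: pd.DataFrame  # canonical columns + r2_explained, f_stat
    config: SelectionConfig

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records["snp"])

    @property
    def mean_f(self) -> float:
        return float(self.records["f_stat"].mean()) if len(self) else float("nan")


_R2_CLIP = 1 - 1e-12


def variance_explained(rec, method: str = "z_n") -> float:
    """Per-SNP phenotypic variance explained, clipped to [0, 1 − 1e−12).

    ``rec`` is a mapping with canonical summary-stat fields. ``eaf_beta``
    computes 2·eaf·(1−eaf)·β² (needs eaf; trait assumed standardized);
    ``z_n`` computes z²/(z² + n − 2) (needs n > 2).
    """
    if method == "eaf_beta":
        eaf = rec["eaf"]
        if pd.isna(eaf):
            raise ValueError("variance_explained(eaf_beta): missing field 'eaf'")
        r2 = 2.0 * eaf * (1.0 - eaf) * rec["beta"] ** 2
    elif method == "z_n":
        n = rec["n"]
        if pd.isna(n):
            raise ValueError("variance_explained(z_n): missing field 'n'")
        if n <= 2:
            raise ValueError("variance_explained(z_n): requires n > 2")
        z = rec["beta"] / rec["se"]
        r2 = z * z / (z * z + n - 2.0)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(np.clip(r2, 0.0, _R2_CLIP))


def f_statistic(r2: float, n: float) -> float:
    """Instrument-strength F = R²(n−2)/(1−R²)."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    if n <= 2:
        raise ValueError("n must be > 2")
    return float(r2 * (n - 2.0) / (1.0 - r2))


def _check_ld(ld: pd.DataFrame) -> pd.DataFrame:
    vals = ld.to_numpy(dtype=float)
    if ld.shape[0] != ld.shape[1] or list(ld.index) != list(ld.columns):
        raise ValueError("LD matrix must be square with identical row/column ids")
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("LD matrix must be symmetric")
    if not np.allclose(np.diag(vals), 1.0, atol=1e-6):
        raise ValueError("LD matrix diagonal must be 1")
    return ld


def clump(records: pd.DataFrame, window_kb: float, r2_threshold: float,
          ld: pd.DataFrame | None = None) -> pd.DataFrame:
    """Greedy p-value clumping.

    Records are visited in ascending p (ties broken by snp id); each
    retained SNP discards every other SNP on the same chromosome within
    ``window_kb`` or, when ``ld`` is given, any SNP with r² ≥
    ``r2_threshold`` against it.  Output order is the retention order, so
    the result is independent of input row order.
    """
    if ld is not None:
        ld = _check_ld(ld)
        missing = set(records["snp"]) - set(ld.index)
        if missing:
            raise ValueError(f"LD matrix missing snp(s): {sorted(missing)[:5]}")
    ordered = records.sort_values(["pval", "snp"], kind="mergesort")
    kept_rows = []
    discarded: set[str] = set()
    for _, row in ordered.iterrows():
        if row["snp"] in discarded:
            continue
        kept_rows.append(row)
        same_chr = ordered["chr"] == row["chr"]
        near = same_chr & (
            (ordered["pos"] - row["pos"]).abs() <= window_kb * 1_000
        )
        hit = near.to_numpy()
        if ld is not None:
            linked = ld.loc[row["snp"], ordered["snp"]].to_numpy() >= r2_threshold
            hit = hit | linked
        discarded.update(ordered["snp"][hit])
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def select_instruments(ss: SummaryStats, config: SelectionConfig | None = None,
                       ld: pd.DataFrame | None = None) -> InstrumentSet:
    """Significance filter, then clump, then per-SNP R²/F, then drop weak F.

    Returns an empty set (with a logged warning) when nothing survives.
    """
    config = config or SelectionConfig()
    if len(ss) == 0:
        raise ValueError("empty summary statistics")
    sig = ss.records[ss.records["pval"] < config.p_threshold]
    if sig.empty:
        logger.warning("%s: no SNP passes p < %g", ss.trait_id, config.p_threshold)
        return InstrumentSet(ss.trait_id, _empty_records(), config)
    pruned = clump(sig, config.clump_window_kb, config.r2_threshold, ld)
    r2 = np.array([variance_explained(row, config.r2_method)
                   for _, row in pruned.iterrows()])
    f = np.array([f_statistic(v, n) for v, n in zip(r2, pruned["n"])])
    pruned = pruned.assign(r2_explained=r2, f_stat=f)
    strong = pruned[pruned["f_stat"] > config.f_min].reset_index(drop=True)
    if strong.empty:
        logger.warning("%s: no instrument with F > %g", ss.trait_id, config.f_min)
    return InstrumentSet(ss.trait_id, strong, config)


def _empty_records() -> pd.DataFrame:
    from .sumstats import CANONICAL_COLUMNS
    return pd.DataFrame(columns=CANONICAL_COLUMNS + ["r2_explained", "f_stat"])
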