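"""GWAS summary-statistics containers and delimited-text I/O.

The canonical on-disk dialect is a tab-separated table with a header row of
canonical column names::

    snp  chr  pos  effect_allele  other_allele  eaf  beta  se  pval  n

``eaf`` may be missing and is written as ``NA``.  Positions are 1-based.
Foreign headers are adapted with a ``column_map`` (canonical name -> column
name in the file).  Rows violating hard invariants (non-positive standard
error, identical alleles, frequencies outside [0, 1], p-values outside
(0, 1]) are dropped with a logged count; a p-value of exactly zero is
clamped to the smallest positive float instead of dropped, so that log-scale
reporting stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]
MANDATORY_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]

#: smallest positive double; p-values of exactly 0 are clamped here
TINY_P = np.nextafter(0.0, 1.0)

_ALLELE_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class TraitMeta:
    """Identity and type of the trait a summary-statistics table describes."""

    trait_id: str
    trait_label: str = ""
    trait_type: str = "continuous"  # {continuous, binary}
    population: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type: {self.trait_type!r}")


@dataclass
class SummaryStats:
    """One trait's per-SNP marginal associations.

    ``records`` is a DataFrame with the canonical columns, in file order;
    ``snp`` values are unique.  ``n_dropped`` counts input rows removed for
    hard invariant violations during reading (provenance metadata).
    """

    meta: TraitMeta
    records: pd.DataFrame
    n_dropped: int = 0
    _by_id: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        snps = self.records["snp"]
        if snps.duplicated().any():
            dups = snps[snps.duplicated()].unique()[:5]
            raise ValueError(f"duplicate snp ids: {list(dups)}")
        self._by_id = {s: i for i, s in enumerate(snps)}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    @property
    def trait_id(self) -> str:
        return self.meta.trait_id

    def get(self, snp_id: str) -> pd.Series:
        """O(1) row lookup by SNP identifier."""
        return self.records.iloc[self._by_id[snp_id]]

    def subset(self, snp_ids) -> "SummaryStats":
        """Rows for ``snp_ids`` (input order preserved); missing ids are skipped."""
        idx = [self._by_id[s] for s in snp_ids if s in self._by_id]
        return SummaryStats(self.meta, self.records.iloc[idx].reset_index(drop=True))


def _coerce_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, int, list[str]]:
    """Normalize types/case, drop invalid rows.  Returns (clean, n_dropped, notes)."""
    notes: list[str] = []
    out = pd.DataFrame(index=df.index)
    out["snp"] = df["snp"].astype(str).str.strip()
    out["chr"] = df["chr"].astype(str).str.strip() if "chr" in df else ""
    out["pos"] = (
        pd.to_numeric(df["pos"], errors="coerce") if "pos" in df else np.nan
    )
    for col in ("effect_allele", "other_allele"):
        out[col] = df[col].astype(str).str.strip().str.upper()
    if "eaf" in df:
        out["eaf"] = pd.to_numeric(df["eaf"], errors="coerce")
    else:
        out["eaf"] = np.nan
    for col in ("beta", "se", "pval"):
        out[col] = pd.to_numeric(df[col], errors="coerce")
    out["n"] = pd.to_numeric(df["n"], errors="coerce") if "n" in df else np.nan

    n_zero_p = int((out["pval"] == 0).sum())
    if n_zero_p:
        notes.append(f"{n_zero_p} p-value(s) of 0 clamped to {TINY_P:g}")
        out.loc[out["pval"] == 0, "pval"] = TINY_P

    alleles_ok = out["effect_allele"].map(
        lambda a: len(a) > 0 and set(a) <= _ALLELE_ALPHABET
    ) & out["other_allele"].map(lambda a: len(a) > 0 and set(a) <= _ALLELE_ALPHABET)
    good = (
        alleles_ok
        & (out["effect_allele"] != out["other_allele"])
        & np.isfinite(out["beta"])
        & (out["se"] > 0)
        & (out["pval"] > 0)
        & (out["pval"] <= 1)
        & (out["eaf"].isna() | ((out["eaf"] >= 0) & (out["eaf"] <= 1)))
        & (out["n"].isna() | (out["n"] > 1))
        & (out["snp"] != "")
    )
    n_dropped = int((~good).sum())
    clean = out[good].reset_index(drop=True)

    # soft check: p consistent with |beta/se| under a two-sided normal
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(clean["beta"] / clean["se"])
        p_implied = 2 * stats.norm.sf(z)
    loose = np.abs(np.log10(np.maximum(p_implied, TINY_P))
                   - np.log10(clean["pval"].to_numpy())) > 1.0
    if loose.any():
        notes.append(
            f"{int(loose.sum())} row(s) with p-value inconsistent with beta/se "
            "(>1 order of magnitude; kept)"
        )
    return clean[CANONICAL_COLUMNS], n_dropped, notes


def read_sumstats(path, trait_meta: TraitMeta, column_map: dict | None = None,
                  sep: str | None = None) -> SummaryStats:
    """Read one delimited summary-statistics table.

    Parameters
    ----------
    path
        Delimited text file with a header row.  ``sep=None`` sniffs the
        delimiter; pass ``"\\t"`` for the canonical dialect.
    trait_meta
        Trait identity attached to the returned container.
    column_map
        Mapping canonical field -> column name in the file, for foreign
        headers; omitted fields are assumed to already use canonical names.

    Raises
    ------
    ValueError
        If the file is empty or a mandatory column is missing.
    """
    import csv

    try:
        raw = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                          keep_default_na=False, na_values=["NA", ""])
    except (pd.errors.EmptyDataError, csv.Error):
        raise ValueError(f"empty or malformed summary-statistics file: {path}"
                         ) from None
    if raw.empty:
        raise ValueError(f"summary-statistics file has no data rows: {path}")
    if column_map:
        missing_src = [v for v in column_map.values() if v not in raw.columns]
        if missing_src:
            raise ValueError(f"column_map names absent from file: {missing_src}")
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column: {col!r} in {path}")
    clean, n_dropped, notes = _coerce_frame(raw)
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    for note in notes:
        logger.warning("%s: %s", path, note)
    return SummaryStats(trait_meta, clean, n_dropped=n_dropped)


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write the canonical tab-separated dialect (missing values as ``NA``).

    Floats are rendered with Python's shortest round-trip ``repr``, so
    ``read_sumstats(write_sumstats(ss))`` reproduces ``ss`` exactly.
    """
    if len(ss) == 0:
        raise ValueError("refusing to write empty SummaryStats")
    df = ss.records.copy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def validation_report(ss: SummaryStats) -> str:
    """Human-readable validation summary for one table."""
    df = ss.records
    lines = [
        f"trait: {ss.meta.trait_id} ({ss.meta.trait_label})",
        f"records: {len(df)}   dropped on read: {ss.n_dropped}",
        f"missing eaf: {int(df['eaf'].isna().sum())}",
        f"missing n:   {int(df['n'].isna().sum())}",
        f"min p: {df['pval'].min():.3g}   median se: {df['se'].median():.3g}",
    ]
    return "\n".join(lines)
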