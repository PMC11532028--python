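"""Allele harmonization of two summary-statistics tables.

Two-sample MR needs the exposure and outcome effect sizes expressed per copy
of the *same* allele.  Tables from different consortia may list the alleles
swapped, report the opposite strand, or both; palindromic SNPs (A/T, G/C)
are strand-ambiguous and can only be oriented by allele frequency.

Rules applied per SNP, in order:

* indel / multi-allelic records -> excluded ``non_snp``;
* SNP absent from the outcome table -> excluded ``missing_in_outcome``;
* palindromic pairs: orientation by frequency — kept only when both
  frequencies are outside ``0.5 ± palindrome_eaf_window`` and fall on the
  same side of 0.5, otherwise excluded ``palindromic_ambiguous`` (missing
  frequency on either side also excludes);
* non-palindromic pairs: matched directly, after swapping effect/other
  (outcome beta sign-flipped, eaf -> 1-eaf), after strand complementation
  (A<->T, C<->G), or after both; unresolvable allele sets are excluded
  ``allele_mismatch``.

A pair needing both complementation and a swap is recorded with action
``flipped_y_sign`` (the sign flip is the substantive change); pure strand
renaming is ``strand_flipped``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SummaryStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-width of the ambiguous-frequency window around 0.5
DEFAULT_PALINDROME_WINDOW = 0.08

ACTIONS = ("kept", "flipped_y_sign", "strand_flipped", "excluded")


@dataclass
class HarmonizedSet:
    """Exposure/outcome betas aligned to a shared effect allele.

    ``pairs`` has one row per input SNP (order preserved) with columns
    ``snp, beta_x, se_x, beta_y, se_y, eaf_x, eaf_y, action, reason``.
    """

    pairs: pd.DataFrame
    exposure_trait_id: str
    outcome_trait_id: str

    @property
    def n_input(self) -> int:
        return len(self.pairs)

    @property
    def n_kept(self) -> int:
        return int((self.pairs["action"] != "excluded").sum())

    def kept(self) -> pd.DataFrame:
        return self.pairs[self.pairs["action"] != "excluded"].reset_index(drop=True)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) over kept pairs."""
        k = self.kept()
        return (k["beta_x"].to_numpy(), k["se_x"].to_numpy(),
                k["beta_y"].to_numpy(), k["se_y"].to_numpy())


def _complement(allele: str) -> str:
    return "".join(COMPLEMENT[b] for b in allele)


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and COMPLEMENT[a1] == a2


def harmonize(exposure: SummaryStats, outcome: SummaryStats, snp_ids,
              palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW,
              ) -> HarmonizedSet:
    """Align outcome betas to the exposure's effect alleles for ``snp_ids``.

    Every id in ``snp_ids`` appears exactly once in the result with a
    definite action.  Ids must be present in the exposure table.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ValueError("empty snp id list")
    missing_x = [s for s in snp_ids if s not in exposure]
    if missing_x:
        raise ValueError(f"snp ids absent from exposure: {missing_x[:5]}")

    w = palindrome_eaf_window
    rows = []
    for sid in snp_ids:
        ex = exposure.get(sid)
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        eaf_x = ex["eaf"]
        base = dict(snp=sid, beta_x=ex["beta"], se_x=ex["se"],
                    beta_y=np.nan, se_y=np.nan, eaf_x=eaf_x, eaf_y=np.nan,
                    action="excluded", reason="")

        if sid not in outcome:
            base["reason"] = "missing_in_outcome"
            rows.append(base)
            continue
        oc = outcome.get(sid)
        ea_y, oa_y = oc["effect_allele"], oc["other_allele"]
        if len(ea_x) != 1 or len(oa_x) != 1 or len(ea_y) != 1 or len(oa_y) != 1:
            base["reason"] = "non_snp"
            rows.append(base)
            continue

        beta_y, se_y, eaf_y = oc["beta"], oc["se"], oc["eaf"]

        if _is_palindromic(ea_x, oa_x):
            if not _is_palindromic(ea_y, oa_y) or {ea_y, oa_y} != {ea_x, oa_x}:
                base["reason"] = "allele_mismatch"
                rows.append(base)
                continue
            if ea_y != ea_x:  # listed in swapped order: flip before the eaf check
                beta_y, eaf_y = -beta_y, (np.nan if pd.isna(eaf_y) else 1 - eaf_y)
            if pd.isna(eaf_x) or pd.isna(eaf_y):
                base["reason"] = "palindromic_ambiguous"
                rows.append(base)
                continue
            outside = abs(eaf_x - 0.5) > w and abs(eaf_y - 0.5) > w
            same_side = (eaf_x - 0.5) * (eaf_y - 0.5) > 0
            if outside and same_side:
                base.update(beta_y=beta_y, se_y=se_y, eaf_y=eaf_y,
                            action="kept", reason="")
            else:
                base["reason"] = "palindromic_ambiguous"
            rows.append(base)
            continue

        # non-palindromic: try the four orientations
        if (ea_y, oa_y) == (ea_x, oa_x):
            action, flip = "kept", False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            action, flip = "flipped_y_sign", True
        elif (ea_y, oa_y) == (_complement(ea_x), _complement(oa_x)):
            action, flip = "strand_flipped", False
        elif (ea_y, oa_y) == (_complement(oa_x), _complement(ea_x)):
            action, flip = "flipped_y_sign", True
        else:
            base["reason"] = "allele_mismatch"
            rows.append(base)
            continue
        if flip:
            beta_y = -beta_y
            eaf_y = np.nan if pd.isna(eaf_y) else 1 - eaf_y
        base.update(beta_y=beta_y, se_y=se_y, eaf_y=eaf_y,
                    action=action, reason="")
        rows.append(base)

    pairs = pd.DataFrame(rows, columns=["snp", "beta_x", "se_x", "beta_y",
                                        "se_y", "eaf_x", "eaf_y", "action",
                                        "reason"])
    return HarmonizedSet(pairs, exposure.trait_id, outcome.trait_id)


def harmonization_report(hs: HarmonizedSet) -> pd.DataFrame:
    """TSV-ready per-SNP report: snp, action, reason."""
    return hs.pairs[["snp", "action", "reason"]].copy()
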