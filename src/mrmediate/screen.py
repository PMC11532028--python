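"""Multi-trait MR screens and reverse-direction analysis.

``run_screen`` loops a battery of exposure GWASs against one outcome:
instrument selection, harmonization, the configured estimators, the full
sensitivity suite, then a pass/fail call per trait.  A trait passes when
its (optionally multiplicity-adjusted) IVW p-value is below ``alpha`` and
neither pleiotropy diagnostic (Egger intercept, MR-PRESSO global) is
significant.  ``reverse_mr`` swaps the exposure and outcome roles to probe
reverse causation with identical machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimators import MREstimate, run_methods
from .harmonize import harmonize
from .instruments import SelectionConfig, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import SummaryStats, TraitMeta, read_sumstats


@dataclass(frozen=True)
class ScreenConfig:
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    alpha: float = 0.05
    adjust: str = "none"  # {none, bonferroni, bh}
    methods: tuple = ("ivw", "egger", "weighted_median",
                      "simple_mode", "weighted_mode")
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.adjust not in ("none", "bonferroni", "bh"):
            raise ValueError(f"unknown adjustment: {self.adjust!r}")


@dataclass
class ScreenRow:
    trait_id: str
    trait_label: str
    nsnp: int
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    ivw_p_adjusted: float | None = None
    passed: bool = False
    status: str = "ok"  # ok | no_instruments | error:<msg>


def row_passes(row: ScreenRow, config: ScreenConfig) -> bool:
    """Recompute the pass flag from the row's own statistics.

    Pass requires adjusted IVW p < alpha, Egger intercept p ≥ alpha and
    PRESSO global p ≥ alpha (diagnostics unavailable at low instrument
    counts do not disqualify).
    """
    if row.status != "ok" or "ivw" not in row.estimates:
        return False
    p = row.ivw_p_adjusted
    if p is None or not p < config.alpha:
        return False
    s = row.sensitivity
    if s is not None:
        if s.egger_intercept_p is not None and s.egger_intercept_p < config.alpha:
            return False
        if s.presso_global_p is not None and s.presso_global_p < config.alpha:
            return False
    return True


def _as_sumstats(obj, fallback_id: str) -> SummaryStats:
    if isinstance(obj, SummaryStats):
        return obj
    return read_sumstats(obj, TraitMeta(trait_id=str(obj)), sep="\t")


def analyze_pair(exposure: SummaryStats, outcome: SummaryStats,
                 config: ScreenConfig) -> ScreenRow:
    """One exposure against one outcome: estimates + sensitivity, no flag."""
    row = ScreenRow(trait_id=exposure.trait_id,
                    trait_label=exposure.meta.trait_label, nsnp=0)
    try:
        inst = select_instruments(exposure, config.selection)
        if len(inst) == 0:
            row.status = "no_instruments"
            return row
        hs = harmonize(exposure, outcome, inst.snp_ids)
        if hs.n_kept < 2:
            row.status = "no_instruments"
            return row
        row.nsnp = hs.n_kept
        feasible = [m for m in config.methods
                    if hs.n_kept >= {"egger": 3, "simple_mode": 3,
                                     "weighted_mode": 3}.get(m, 2)]
        row.estimates = run_methods(hs, feasible, ivw_model=config.ivw_model,
                                    n_boot=config.n_boot, seed=config.seed)
        row.sensitivity = sensitivity_report(
            hs, n_sim=config.presso_n_sim, seed=config.seed,
            ivw_model=config.ivw_model)
    except ValueError as err:  # isolate per-trait failures
        row.status = f"error:{err}"
    return row


def run_screen(exposures, outcome, config: ScreenConfig | None = None,
               ) -> list[ScreenRow]:
    """Screen each exposure (paths or SummaryStats) against the outcome.

    Rows come back sorted by IVW p-value, with the multiplicity adjustment
    of ``config.adjust`` applied across the screened traits before the
    pass/fail call.
    """
    config = config or ScreenConfig()
    exposures = list(exposures)
    if not exposures:
        raise ValueError("empty exposure list")
    outcome_ss = _as_sumstats(outcome, "outcome")
    rows = [analyze_pair(_as_sumstats(e, f"exposure{i}"), outcome_ss, config)
            for i, e in enumerate(exposures)]

    ok = [r for r in rows if r.status == "ok" and "ivw" in r.estimates]
    if ok:
        pvals = np.array([r.estimates["ivw"].pval for r in ok])
        if config.adjust == "none":
            adj = pvals
        else:
            method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[config.adjust]
            adj = multipletests(pvals, method=method)[1]
        for r, p in zip(ok, adj):
            r.ivw_p_adjusted = float(p)
    for r in rows:
        r.passed = row_passes(r, config)
    rows.sort(key=lambda r: (r.estimates["ivw"].pval
                             if "ivw" in r.estimates else np.inf,
                             r.trait_id))
    return rows


def reverse_mr(outcome, exposure, config: ScreenConfig | None = None,
               ) -> ScreenRow:
    """Reverse-direction MR: the former outcome becomes the exposure."""
    return run_screen([outcome], exposure, config)[0]


_REPORT_COLUMNS = ["trait", "trait_label", "nsnp", "method", "beta", "se",
                   "or", "ci_low", "ci_high", "p", "p_adjusted", "Q", "Q_p",
                   "egger_intercept", "egger_intercept_p", "presso_p",
                   "passed", "status"]


def report_frame(rows: list[ScreenRow]) -> pd.DataFrame:
    """Long-format report: one line per (trait, method)."""
    out = []
    for r in rows:
        s = r.sensitivity
        base = dict(trait=r.trait_id, trait_label=r.trait_label, nsnp=r.nsnp,
                    Q=s.q_stat if s else np.nan,
                    Q_p=s.q_pval if s else np.nan,
                    egger_intercept=(s.egger_intercept if s else np.nan),
                    egger_intercept_p=(s.egger_intercept_p if s else np.nan),
                    presso_p=(s.presso_global_p if s else np.nan),
                    passed=r.passed, status=r.status)
        if not r.estimates:
            out.append({**base, "method": "", "beta": np.nan, "se": np.nan,
                        "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan, "p_adjusted": np.nan})
        for method, est in r.estimates.items():
            out.append({**base, "method": method, "beta": est.beta,
                        "se": est.se, "or": est.or_, "ci_low": est.ci_low,
                        "ci_high": est.ci_high, "p": est.pval,
                        "p_adjusted": (r.ivw_p_adjusted
                                       if method == "ivw" else np.nan)})
    return pd.DataFrame(out, columns=_REPORT_COLUMNS)


def render_report(rows: list[ScreenRow], path, fmt: str = "tsv") -> None:
    """Write the screen report as TSV or JSON with a fixed column order."""
    df = report_frame(rows)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1,
                      default=float)
    else:
        raise ValueError(f"unknown report format: {fmt!r}")
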