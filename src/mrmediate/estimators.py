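"""Causal-effect estimators for two-sample MR.

Given harmonized per-SNP effects (β_xj, β_yj) with outcome standard errors
se_yj, every estimator here is a different way of pooling the per-SNP Wald
ratios β_yj/β_xj:

* **IVW** — inverse-variance-weighted meta-analysis of the ratios,
  equivalently weighted least squares of β_y on β_x through the origin with
  weights 1/se_y².  The multiplicative random-effects variant inflates the
  standard error by √(Q/(m−1)) when Cochran's Q exceeds its degrees of
  freedom.
* **MR-Egger** — the same regression with a free intercept; the slope is
  robust to directional pleiotropy under InSIDE, and the intercept estimates
  the average pleiotropic effect.
* **Weighted median** — the 50% weighted quantile of the ratio distribution;
  consistent when instruments carrying more than half the weight are valid.
* **Simple / weighted mode** — the argmax of a kernel-smoothed ratio
  density; consistent when the largest cluster of instruments is valid.

Median and mode standard errors come from a parametric bootstrap: β_x* and
β_y* are redrawn normal around the observed values with the observed
standard errors and the estimator recomputed.

Binary outcomes are on the log-odds scale, so estimates exponentiate to
odds ratios; ``to_or_scale`` applies the 95% Wald interval with the normal
quantile 1.959964.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet

Z95 = 1.959964

METHODS = ("wald_ratio", "ivw", "egger", "weighted_median",
           "simple_mode", "weighted_mode")


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate, on the beta and odds-ratio scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_low: float
    or_high: float
    nsnp: int


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope estimate plus the intercept (pleiotropy) test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _two_sided_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _make_estimate(method: str, beta: float, se: float, nsnp: int) -> MREstimate:
    lo, hi = beta - Z95 * se, beta + Z95 * se
    p = _two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(lo), ci_high=float(hi), pval=p,
                      or_=float(np.exp(beta)), or_low=float(np.exp(lo)),
                      or_high=float(np.exp(hi)), nsnp=int(nsnp))


def to_or_scale(beta: float, se: float) -> tuple[float, float, float, float]:
    """(OR, OR low, OR high, two-sided Wald p) for a log-OR estimate."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (float(np.exp(beta)), float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)), _two_sided_p(beta / se))


def p_from_or_ci(or_: float, or_low: float, or_high: float) -> float:
    """Two-sided Wald p reconstructed from a printed OR and its 95% CI.

    The CI implies se = (ln OR_high − ln OR_low) / (2·1.959964); the p-value
    follows from z = ln OR / se.
    """
    if not 0 < or_low < or_ < or_high:
        raise ValueError("need 0 < or_low < or_ < or_high")
    se = (np.log(or_high) - np.log(or_low)) / (2 * Z95)
    return _two_sided_p(np.log(or_) / se)


# ---------------------------------------------------------------------------
# per-SNP ratios

def ratio_se(beta_x, se_x, beta_y, se_y, second_order: bool = False):
    """Standard error of the Wald ratio β_y/β_x.

    First order (default) ignores exposure noise: se_y/|β_x|.  The
    second-order form adds the β_x term of the delta expansion.
    """
    beta_x = np.asarray(beta_x, dtype=float)
    if second_order:
        return np.sqrt(se_y ** 2 / beta_x ** 2
                       + beta_y ** 2 * se_x ** 2 / beta_x ** 4)
    return np.asarray(se_y, dtype=float) / np.abs(beta_x)


def wald_ratio(pair, second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate β_y/β_x with delta-method se."""
    bx, by = float(pair["beta_x"]), float(pair["beta_y"])
    if bx == 0:
        raise ValueError("null instrument: beta_x = 0")
    se = float(ratio_se(bx, float(pair["se_x"]), by, float(pair["se_y"]),
                        second_order))
    return _make_estimate("wald_ratio", by / bx, se, 1)


# ---------------------------------------------------------------------------
# IVW

def _ivw_arrays(bx, by, sy, model: str) -> tuple[float, float, float]:
    """(beta, se, Q) for origin-constrained WLS with weights 1/se_y²."""
    w = 1.0 / sy ** 2
    s_xx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / s_xx
    se = 1.0 / np.sqrt(s_xx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if model == "multiplicative_random":
        m = len(bx)
        se *= max(1.0, np.sqrt(q / (m - 1))) if m > 1 else 1.0
    elif model != "fixed":
        raise ValueError(f"unknown IVW model: {model!r}")
    return beta, float(se), q


def ivw(hs: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over the kept pairs.

    ``model``: ``fixed`` or ``multiplicative_random`` (default; the se is
    inflated by √(Q/(m−1)) when heterogeneity exceeds its expectation).
    """
    bx, _, by, sy = hs.arrays()
    if len(bx) < 2:
        raise ValueError("IVW requires at least 2 instruments")
    beta, se, _ = _ivw_arrays(bx, by, sy, model)
    return _make_estimate("ivw", beta, se, len(bx))


# ---------------------------------------------------------------------------
# MR-Egger

def _egger_arrays(bx, by, sy):
    """Weighted regression with intercept on sign-oriented inputs.

    Returns (slope, slope_se, intercept, intercept_se, m).
    """
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy ** 2
    sw = w.sum()
    sx, sy_ = (w * x).sum(), (w * y).sum()
    sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * sxx - sx * sx
    if det <= 0 or not np.isfinite(det) or det < 1e-12 * sw * sxx:
        raise ValueError("degenerate design: exposure betas collinear with intercept")
    slope = (sw * sxy - sx * sy_) / det
    intercept = (sxx * sy_ - sx * sxy) / det
    m = len(x)
    resid = y - intercept - slope * x
    q = float((w * resid ** 2).sum())
    sigma2 = max(1.0, q / (m - 2)) if m > 2 else 1.0
    slope_se = np.sqrt(sigma2 * sw / det)
    intercept_se = np.sqrt(sigma2 * sxx / det)
    return float(slope), float(slope_se), float(intercept), float(intercept_se), m


def egger(hs: HarmonizedSet) -> EggerResult:
    """MR-Egger regression: pleiotropy-robust slope and intercept test."""
    bx, _, by, sy = hs.arrays()
    if len(bx) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    slope, slope_se, inter, inter_se, m = _egger_arrays(bx, by, sy)
    return EggerResult(
        slope=_make_estimate("egger", slope, slope_se, m),
        intercept=inter, intercept_se=inter_se,
        intercept_p=_two_sided_p(inter / inter_se),
    )


# ---------------------------------------------------------------------------
# weighted median

def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


def _parametric_boot(hs_arrays, estimator, n_boot: int, seed) -> float:
    """sd of ``estimator`` over parametric resamples of (β_x, β_y)."""
    bx, sx, by, sy = hs_arrays
    rng = np.random.default_rng(seed)
    sx = np.where(np.isfinite(sx), sx, 0.0)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + rng.standard_normal(bx.size) * sx
        bys = by + rng.standard_normal(by.size) * sy
        est[b] = estimator(bxs, bys, sy)
    return float(est.std(ddof=1))


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median estimate; se from a seeded parametric bootstrap."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    bx, sx, by, sy = hs.arrays()
    if len(bx) < 2:
        raise ValueError("weighted median requires at least 2 instruments")

    def estimate(bx_, by_, sy_):
        r = by_ / bx_
        w = 1.0 / ratio_se(bx_, None, by_, sy_) ** 2
        return _weighted_median(r, w)

    beta = estimate(bx, by, sy)
    se = _parametric_boot((bx, sx, by, sy), estimate, n_boot, seed)
    return _make_estimate("weighted_median", beta, se, len(bx))


# ---------------------------------------------------------------------------
# mode-based estimate

def _mode_point(ratios: np.ndarray, weights: np.ndarray,
                bandwidth_factor: float) -> float:
    w = weights / weights.sum()
    sd = ratios.std(ddof=1) if ratios.size > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    disp = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = bandwidth_factor * 0.9 * disp * ratios.size ** (-0.2)
    if h <= 0:
        return float(ratios[0])  # all ratios identical
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = (w[:, None] * stats.norm.pdf((grid[None, :] - ratios[:, None]) / h)
            ).sum(axis=0)
    # np.argmax takes the first maximum; the grid is ascending, so ties
    # break toward the smaller ratio
    return float(grid[np.argmax(dens)])


def mode_estimate(hs: HarmonizedSet, weighted: bool = False,
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MREstimate:
    """Simple (equal-weight) or weighted mode of the ratio density."""
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    bx, sx, by, sy = hs.arrays()
    if len(bx) < 3:
        raise ValueError("mode estimators require at least 3 instruments")

    def estimate(bx_, by_, sy_):
        r = by_ / bx_
        if weighted:
            w = 1.0 / ratio_se(bx_, None, by_, sy_) ** 2
        else:
            w = np.ones_like(r)
        return _mode_point(r, w, bandwidth_factor)

    beta = estimate(bx, by, sy)
    se = _parametric_boot((bx, sx, by, sy), estimate, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return _make_estimate(method, beta, se, len(bx))


def run_methods(hs: HarmonizedSet, methods=("ivw",), ivw_model: str =
                "multiplicative_random", n_boot: int = 1000,
                seed: int | None = None) -> dict[str, MREstimate]:
    """Run a list of estimators on one harmonized set, keyed by method name."""
    out: dict[str, MREstimate] = {}
    for m in methods:
        if m == "ivw":
            out[m] = ivw(hs, model=ivw_model)
        elif m == "egger":
            out[m] = egger(hs).slope
        elif m == "weighted_median":
            out[m] = weighted_median(hs, n_boot=n_boot, seed=seed)
        elif m == "simple_mode":
            out[m] = mode_estimate(hs, weighted=False, n_boot=n_boot, seed=seed)
        elif m == "weighted_mode":
            out[m] = mode_estimate(hs, weighted=True, n_boot=n_boot, seed=seed)
        else:
            raise ValueError(f"unknown method: {m!r}")
    return out
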