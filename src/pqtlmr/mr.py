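"""Two-sample Mendelian randomization estimators and tests.

All estimators consume harmonized exposure/outcome effect pairs
(:class:`~pqtlmr.instruments.InstrumentSet`).  Per-instrument ratio
estimates use first-order delta-method standard errors, the standard
two-sample MR default.  Effects on binary outcomes are log odds ratios;
results carry the OR and its 95% CI.

Estimators
----------
wald_ratio
    Single-instrument ratio estimate beta_y / beta_x.
ivw
    Inverse-variance-weighted estimate: weighted regression of beta_y on
    beta_x through the origin with weights 1/se_y^2.  With one instrument
    this reduces exactly to the Wald ratio.
mr_egger
    Weighted regression with a free intercept; the intercept tests
    directional pleiotropy.  Instruments are orientated so beta_x >= 0.
weighted_median
    Median of the weighted empirical distribution of ratio estimates;
    consistent when instruments carrying >= 50% of the weight are valid.
    SE by seeded parametric bootstrap.
cochran_q
    Heterogeneity of per-instrument ratios around the IVW estimate.
smr_test
    Summary-data-based MR chi-square test at a single variant,
    T = z_x^2 z_y^2 / (z_x^2 + z_y^2) ~ chi^2(1) under the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import Instrument, InstrumentSet

__all__ = [
    "MRResult",
    "HeterogeneityResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "smr_test",
    "bonferroni_threshold",
    "format_or_ci",
]

_Z95 = 1.96


@dataclass
class MRResult:
    """One method's estimate for one exposure-outcome pair."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    model: str | None = None
    seed: int | None = None

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - _Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + _Z95 * self.se)


@dataclass
class HeterogeneityResult:
    """Cochran's Q with df = n_snps - 1."""

    q: float
    df: int
    p: float


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2 * stats.norm.sf(abs(beta) / se))


def wald_ratio(inst: Instrument) -> MRResult:
    """Single-instrument ratio estimate with first-order delta SE."""
    if inst.beta_x == 0:
        raise ValueError("wald ratio undefined for beta_x = 0")
    beta = inst.beta_y / inst.beta_x
    se = inst.se_y / abs(inst.beta_x)
    return MRResult("wald", beta, se, _norm_p(beta, se), n_snps=1)


def _ratio_arrays(insts: InstrumentSet):
    bx, sx, by, sy = insts.arrays()
    if np.any(bx == 0):
        raise ValueError("beta_x = 0 instrument present")
    return bx, sx, by, sy


def ivw(insts: InstrumentSet, model: str = "auto") -> MRResult:
    """Inverse-variance-weighted estimate.

    ``model``: "fixed", "multiplicative_random", or "auto" (fixed-effect
    for <= 3 instruments, multiplicative random effects otherwise).  The
    multiplicative model inflates the SE by max(1, sqrt(Q/df)).
    """
    if len(insts) == 0:
        raise ValueError("empty instrument set")
    bx, _, by, sy = _ratio_arrays(insts)
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se = math.sqrt(1.0 / denom)
    if model == "auto":
        model = "fixed" if len(insts) <= 3 else "multiplicative_random"
    if model == "multiplicative_random" and len(insts) >= 2:
        het = cochran_q(insts)
        se *= max(1.0, math.sqrt(het.q / het.df))
    elif model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    return MRResult("ivw", beta, se, _norm_p(beta, se), n_snps=len(insts), model=model)


def mr_egger(insts: InstrumentSet) -> MRResult:
    """MR-Egger regression: weighted fit of beta_y = a + b * beta_x.

    Instruments are orientated so every beta_x >= 0 before the fit
    (Egger's convention).  SEs carry the multiplicative residual scale
    max(1, sqrt(RSS_w / (n - 2))); p-values use a t reference with n - 2
    degrees of freedom.
    """
    if len(insts) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, _, by, sy = _ratio_arrays(insts)
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2

    sw = w.sum()
    sx_ = np.sum(w * bx)
    sy_ = np.sum(w * by)
    sxx = np.sum(w * bx * bx)
    sxy = np.sum(w * bx * by)
    det = sw * sxx - sx_**2
    slope = (sw * sxy - sx_ * sy_) / det
    intercept = (sxx * sy_ - sx_ * sxy) / det

    resid = by - intercept - slope * bx
    n = len(insts)
    scale = max(1.0, math.sqrt(float(np.sum(w * resid**2)) / (n - 2)))
    se_slope = math.sqrt(sw / det) * scale
    se_int = math.sqrt(sxx / det) * scale
    tdist = stats.t(df=n - 2)
    p_slope = float(2 * tdist.sf(abs(slope) / se_slope))
    p_int = float(2 * tdist.sf(abs(intercept) / se_int))
    return MRResult(
        "egger", float(slope), se_slope, p_slope, n_snps=n,
        egger_intercept=float(intercept), egger_intercept_p=p_int,
    )


def _weighted_median_estimate(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2  # midpoint cumulative weights
    if s[0] >= 0.5:
        return float(v[0])
    if s[-1] < 0.5:
        return float(v[-1])
    k = int(np.searchsorted(s, 0.5, side="left"))
    if s[k] == 0.5:
        return float(v[k])
    # interpolate the weighted empirical CDF between the straddling points
    return float(v[k - 1] + (v[k] - v[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(insts: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median MR estimate with parametric-bootstrap SE."""
    if len(insts) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    bx, sx, by, sy = _ratio_arrays(insts)
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    weights = 1.0 / se_ratio**2
    beta = _weighted_median_estimate(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = np.finfo(float).tiny
        rb = byb / bxb
        boots[b] = _weighted_median_estimate(rb, (bxb / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    return MRResult(
        "weighted_median", beta, se, _norm_p(beta, se), n_snps=len(insts), seed=seed
    )


def cochran_q(insts: InstrumentSet) -> HeterogeneityResult:
    """Cochran's Q over per-instrument ratios with first-order weights."""
    if len(insts) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    bx, _, by, sy = _ratio_arrays(insts)
    theta = by / bx
    w = (bx / sy) ** 2
    theta_ivw = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_ivw) ** 2))
    df = len(insts) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def smr_test(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MRResult:
    """Summary-data-based MR test at a single (lead cis-pQTL) variant.

    T = z_x^2 z_y^2 / (z_x^2 + z_y^2), referred to chi-square(1).  The
    point estimate is the ratio beta_y / beta_x with the full delta SE
    |beta| sqrt(1/z_x^2 + 1/z_y^2).
    """
    if se_x <= 0 or se_y <= 0:
        raise ValueError("standard errors must be positive")
    if beta_x == 0:
        raise ValueError("beta_x = 0")
    zx, zy = beta_x / se_x, beta_y / se_y
    if zx == 0 and zy == 0:
        raise ValueError("both z-scores are zero")
    t = zx**2 * zy**2 / (zx**2 + zy**2)
    p = float(stats.chi2.sf(t, 1))
    beta = beta_y / beta_x
    se = abs(beta) * math.sqrt(1 / zx**2 + 1 / zy**2) if zy != 0 else se_y / abs(beta_x)
    return MRResult("smr", beta, se, p, n_snps=1)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def format_or_ci(beta: float, se: float) -> str:
    """Display an effect as ``OR (low–high)`` rounded to 2 decimals."""
    lo = math.exp(beta - _Z95 * se)
    hi = math.exp(beta + _Z95 * se)
    return f"{math.exp(beta):.2f} ({lo:.2f}–{hi:.2f})"
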