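"""Core two-sample MR estimators and heterogeneity diagnostics.

Implements the Wald ratio, inverse-variance-weighted (IVW) combination,
MR-Egger regression, the weighted-median estimator, Cochran's Q / I²
heterogeneity statistics, leave-one-out re-estimation, and the
per-doubling-of-odds rescaling for binary exposures.

All estimators consume a :class:`~twosample_mr.harmonize.HarmonizedSet`.
Causal effects are reported on the log-odds scale for binary outcomes
(``or_scale`` exponentiates the estimate and its CI).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet, HarmonizedVariant

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

IVWModel = Literal["fixed", "multiplicative_random"]


class InsufficientInstrumentsError(ValueError):
    """Raised when an estimator receives fewer variants than it needs."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a Wald ratio is requested for a null exposure effect."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its uncertainty and provenance.

    ``beta`` is the causal effect per exposure unit on the outcome's log-odds
    scale; ``or_scale`` gives the exponentiated (OR) triple.  Egger fits also
    carry the intercept triple as a directional-pleiotropy test.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure_type: str = "continuous"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if self.se > 0 and not self.ci_low < self.ci_high:
            raise ValueError("ci_low must be below ci_high")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) — the estimate exponentiated."""
        return (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))

    def summary(self) -> str:
        o, lo, hi = self.or_scale
        return (
            f"{self.method}: OR {o:.3f} (95% CI {lo:.3f}-{hi:.3f}; "
            f"p = {self.pvalue:.3g}; n_snps = {self.n_snps})"
        )


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its degrees of freedom, I² fraction, and chi-square p."""

    Q: float
    df: int
    I2: float
    pvalue: float


def _normal_estimate(
    method: str, beta: float, se: float, n_snps: int, exposure_type: str, **kw
) -> MREstimate:
    z = abs(beta) / se if se > 0 else math.inf
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - 1.959963984540054 * se,
        ci_high=beta + 1.959963984540054 * se,
        pvalue=float(2.0 * stats.norm.sf(z)),
        n_snps=n_snps,
        exposure_type=exposure_type,
        **kw,
    )


def _arrays(s: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([v.beta_exp for v in s.variants])
    sx = np.array([v.se_exp for v in s.variants])
    by = np.array([v.beta_out for v in s.variants])
    sy = np.array([v.se_out for v in s.variants])
    return bx, sx, by, sy


def wald_ratio(v: HarmonizedVariant, exposure_type: str = "continuous") -> MREstimate:
    """Single-variant causal estimate: outcome effect over exposure effect.

    The SE uses the first-order delta method, ``se_out / |beta_exp|``
    (exposure-side uncertainty ignored, as is conventional for strong
    instruments).
    """
    if v.beta_exp == 0:
        raise UndefinedRatioError(f"{v.rsid}: exposure beta is zero")
    beta = v.beta_out / v.beta_exp
    se = v.se_out / abs(v.beta_exp)
    return _normal_estimate(f"Wald ratio ({v.rsid})", beta, se, 1, exposure_type)


def ivw(
    s: HarmonizedSet,
    model: IVWModel = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted combination of per-variant Wald ratios.

    Algebraically identical to a zero-intercept weighted regression of
    outcome betas on exposure betas with weights ``1/se_out²``.  The fixed
    model takes ``se = (Σ w)^(-1/2)``; the multiplicative random-effects
    model scales that SE by the residual standard deviation of the
    regression (no lower floor), which inflates the SE under heterogeneity.
    """
    n = len(s.variants)
    if n == 0:
        raise InsufficientInstrumentsError("empty instrument set")
    if n == 1:
        logger.info("single instrument: IVW delegates to the Wald ratio")
        return wald_ratio(s.variants[0], getattr(s, "exposure_type", "continuous"))
    bx, _, by, sy = _arrays(s)
    if np.any(bx == 0):
        bad = s.variants[int(np.argmax(bx == 0))].rsid
        raise UndefinedRatioError(f"{bad}: exposure beta is zero")

    w = bx**2 / sy**2  # ratio-scale weights
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if model == "fixed":
        se = se_fixed
    elif model == "multiplicative_random":
        # residual sd of the zero-intercept weighted regression, df = n - 1
        rss = float(np.sum((by - beta * bx) ** 2 / sy**2))
        sigma = math.sqrt(rss / (n - 1))
        se = se_fixed * sigma
    else:
        raise ValueError(f"unknown IVW model {model!r}")
    label = "IVW" if model == "multiplicative_random" else "IVW (fixed)"
    return _normal_estimate(label, beta, se, n, getattr(s, "exposure_type", "continuous"))


def mr_egger(s: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure betas with a free
    intercept.

    The slope is the pleiotropy-adjusted causal estimate; an intercept
    distinguishable from zero indicates directional pleiotropy.  Exposure
    effects are re-oriented positive internally (flipping the paired outcome
    beta), weights are ``1/se_out²``, SEs carry multiplicative residual
    scaling, and inference uses the t distribution with ``n - 2`` df.
    """
    n = len(s.variants)
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 variants, got {n}")
    bx, _, by, sy = _arrays(s)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    # closed-form weighted simple regression (numerically stable for
    # tightly clustered exposure betas)
    sw = w.sum()
    xbar = float((w * bx).sum() / sw)
    ybar = float((w * by).sum() / sw)
    sxx = float((w * (bx - xbar) ** 2).sum())
    if sxx <= 0:
        raise InsufficientInstrumentsError("no spread in exposure betas")
    slope = float((w * (bx - xbar) * (by - ybar)).sum() / sxx)
    inter = ybar - slope * xbar
    resid = by - inter - slope * bx
    df = n - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    se_slope = math.sqrt(sigma2 / sxx)
    se_inter = math.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx))

    tq = float(stats.t.ppf(0.975, df))
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    p_inter = float(2.0 * stats.t.sf(abs(inter) / se_inter, df))
    return MREstimate(
        method="MR-Egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pvalue=p_slope,
        n_snps=n,
        exposure_type=getattr(s, "exposure_type", "continuous"),
        intercept=inter,
        intercept_se=se_inter,
        intercept_p=p_inter,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Half-weight-centred weighted median with linear interpolation."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    centred = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, centred, v))


def weighted_median(
    s: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator: consistent if instruments carrying at least
    half the weight are valid.

    Wald ratios are ordered and the estimate is read at cumulative
    (half-weight-centred) inverse-variance weight 0.5.  The SE comes from a
    seeded parametric bootstrap that redraws both study betas from normal
    distributions with their reported SEs.
    """
    n = len(s.variants)
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 variants, got {n}")
    bx, sx, by, sy = _arrays(s)
    if np.any(bx == 0):
        raise UndefinedRatioError("exposure beta of zero in instrument set")
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    weights = 1.0 / se_ratio**2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0
        r_b = by_b[ok] / bx_b[ok]
        w_b = (np.abs(bx_b[ok]) / sy[ok]) ** 2
        boot[b] = _weighted_median(r_b, w_b)
    se = float(np.std(boot, ddof=1))
    return _normal_estimate(
        "Weighted median", beta, se, n, getattr(s, "exposure_type", "continuous")
    )


def cochrans_q(s: HarmonizedSet, beta_ref: float) -> HeterogeneityStats:
    """Cochran's Q of the per-variant Wald ratios about a reference estimate.

    ``Q = Σ w_i (r_i - beta_ref)²`` with IVW weights; ``I² = max(0, (Q-df)/Q)``
    quantifies the fraction of dispersion beyond sampling noise.
    """
    n = len(s.variants)
    if n < 2:
        raise InsufficientInstrumentsError("heterogeneity needs >= 2 variants")
    bx, _, by, sy = _arrays(s)
    w = bx**2 / sy**2
    ratios = by / bx
    Q = float(np.sum(w * (ratios - beta_ref) ** 2))
    df = n - 1
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return HeterogeneityStats(Q=Q, df=df, I2=I2, pvalue=float(stats.chi2.sf(Q, df)))


def leave_one_out(
    s: HarmonizedSet, rsid: str, model: IVWModel = "multiplicative_random"
) -> MREstimate:
    """IVW estimate with one named variant removed."""
    reduced = s.without(rsid)
    if len(reduced.variants) < 1:
        raise InsufficientInstrumentsError("no variants left after removal")
    est = ivw(reduced, model=model)
    return replace(est, method=f"{est.method} (without {rsid})")


def leave_one_out_sweep(
    s: HarmonizedSet, model: IVWModel = "multiplicative_random"
) -> dict[str, MREstimate]:
    """Full leave-one-out analysis: one reduced-set IVW estimate per variant."""
    return {v.rsid: leave_one_out(s, v.rsid, model=model) for v in s.variants}


def per_doubling(est: MREstimate) -> MREstimate:
    """Rescale a binary-exposure estimate to 'per doubling of odds' units.

    Multiplies beta, SE and CI bounds by ln 2 ≈ 0.693 before any
    exponentiation, so the OR reads as the effect of doubling the prevalence
    odds of the exposure.  The p-value is scale-invariant and unchanged.
    """
    if est.exposure_type != "binary":
        raise ValueError("per-doubling rescaling applies to binary exposures only")
    return replace(
        est,
        method=f"{est.method} (per doubling)",
        beta=est.beta * LN2,
        se=est.se * LN2,
        ci_low=est.ci_low * LN2,
        ci_high=est.ci_high * LN2,
        intercept=est.intercept * LN2 if est.intercept is not None else None,
        intercept_se=est.intercept_se * LN2 if est.intercept_se is not None else None,
    )


def estimates_frame(estimates) -> "pd.DataFrame":  # noqa: F821
    """Tidy table (method, beta, se, ci, p, OR triple, n_snps) for export."""
    import pandas as pd

    rows = []
    for e in estimates:
        o, lo, hi = e.or_scale
        rows.append(
            {
                "method": e.method,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pvalue": e.pvalue,
                "odds_ratio": o,
                "or_ci_low": lo,
                "or_ci_high": hi,
                "n_snps": e.n_snps,
            }
        )
    return pd.DataFrame(rows)
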