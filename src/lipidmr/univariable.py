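"""Univariable two-sample Mendelian randomization estimators.

Given J harmonized variants with exposure associations bx_j (SE sx_j) and
outcome associations by_j (SE sy_j), the causal slope theta of the exposure
on the outcome (log odds per 1 SD exposure for a binary outcome) is estimated
by:

* Wald ratio — single variant, theta = by/bx with first-order delta SE.
* IVW — zero-intercept weighted regression of by on bx with weights 1/sy^2;
  equivalent to the inverse-variance weighted meta-analysis of Wald ratios.
  A multiplicative random-effects model inflates the SE by sqrt(phi) with
  phi = max(1, Q/(J-1)); fixed effects available by flag.
* MR-Egger — same regression with a free intercept after orienting every
  variant to its exposure-increasing allele; the intercept estimates average
  directional pleiotropy, the slope is the causal estimate (consistent under
  the InSIDE assumption).
* Weighted median — the 50%-weight point of the ordered per-variant ratio
  estimates, consistent when at least half the weight comes from valid
  instruments; SE from a parametric bootstrap.

Confidence intervals use normal quantiles; p-values are two-sided normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_data import HarmonizedSet

__all__ = ["MREstimate", "wald_ratio", "ivw", "egger", "weighted_median"]

_Z95 = stats.norm.isf(0.025)


@dataclass
class MREstimate:
    """A causal-effect estimate on the outcome scale (log odds per SD)."""

    method: str
    theta: float
    se: float
    n_variants: int
    intercept: float | None = None
    intercept_se: float | None = None
    q_statistic: float | None = None
    q_df: int | None = None
    phi: float | None = None

    @property
    def ci_low(self) -> float:
        return self.theta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.theta + _Z95 * self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.theta) / self.se))

    @property
    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, lower, upper) per 1 SD exposure increase."""
        return (math.exp(self.theta), math.exp(self.ci_low), math.exp(self.ci_high))

    @property
    def intercept_p(self) -> float | None:
        if self.intercept is None:
            return None
        return float(2.0 * stats.norm.sf(abs(self.intercept) / self.intercept_se))

    def to_dict(self) -> dict:
        orr, lo, hi = self.odds_ratio
        d = {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "or": orr,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "n_variants": self.n_variants,
            "q_statistic": self.q_statistic,
            "q_df": self.q_df,
            "phi": self.phi,
        }
        if self.intercept is not None:
            d.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_p=self.intercept_p,
            )
        return d


def _unpack(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, HarmonizedSet):
        return data.single()
    bx, sx, by, sy = data
    return (
        np.asarray(bx, float),
        np.asarray(sx, float),
        np.asarray(by, float),
        np.asarray(sy, float),
    )


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-variant ratio estimate theta = by/bx, se = sy/|bx|.

    The first-order delta SE ignores exposure-side uncertainty, matching the
    1/sy^2 weighting convention used by the multi-variant estimators.
    """
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    return MREstimate(
        method="wald",
        theta=by / bx,
        se=sy / abs(bx),
        n_variants=1,
    )


def ivw(data, effects: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate (zero-intercept weighted regression).

    ``effects="random"`` applies the multiplicative random-effects SE
    inflation sqrt(max(1, Q/(J-1))); ``"fixed"`` reports the unscaled SE.
    """
    if effects not in {"fixed", "random"}:
        raise ValueError(f"effects must be 'fixed' or 'random', got {effects!r}")
    bx, sx, by, sy = _unpack(data)
    J = bx.size
    if J == 0:
        raise ValueError("no variants")
    if np.all(bx == 0):
        raise np.linalg.LinAlgError("all exposure betas zero: singular design")
    w = sy ** -2.0
    sxx = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    df = J - 1
    phi = max(1.0, q / df) if df > 0 else 1.0
    se = se_fixed * math.sqrt(phi) if effects == "random" else se_fixed
    return MREstimate(
        method=f"ivw-{effects}",
        theta=theta,
        se=se,
        n_variants=J,
        q_statistic=q,
        q_df=df,
        phi=phi,
    )


def egger(data, effects: str = "random") -> MREstimate:
    """MR-Egger regression: weighted fit of by on bx with a free intercept.

    Rows are first oriented so every bx_j > 0 (flipping bx and by together,
    which is an allele relabelling and leaves the model invariant).  The
    intercept alpha0 estimates average directional pleiotropy; its two-sided
    p-value is the pleiotropy test.
    """
    bx, sx, by, sy = _unpack(data)
    keep = bx != 0
    bx, by, sy = bx[keep], by[keep], sy[keep]
    J = bx.size
    if J < 3:
        raise ValueError(f"MR-Egger needs at least 3 variants, got {J}")
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip

    w = sy ** -2.0
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx * swx
    if det <= 0:
        raise np.linalg.LinAlgError("singular MR-Egger design (constant bx)")
    slope = (sw * swxy - swx * swy) / det
    alpha0 = (swxx * swy - swx * swxy) / det
    resid = by - alpha0 - slope * bx
    q = float(np.sum(w * resid ** 2))
    df = J - 2
    phi = max(1.0, q / df) if df > 0 else 1.0
    scale = phi if effects == "random" else 1.0
    se_slope = math.sqrt(scale * sw / det)
    se_alpha = math.sqrt(scale * swxx / det)
    return MREstimate(
        method="egger",
        theta=slope,
        se=se_slope,
        n_variants=J,
        intercept=alpha0,
        intercept_se=se_alpha,
        q_statistic=q,
        q_df=df,
        phi=phi,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50%-weight point of the ratio distribution.

    Weights are normalized to sum 1; with ratios sorted ascending and S_k the
    cumulative weight, the rank of ratio k is p_k = S_k - w_k/2 and the
    estimate interpolates linearly across the two ranks bracketing 0.5.
    Ties in ratios are broken by a stable sort, so input order (variant ID
    order) decides.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - 0.5 * w
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(
    data,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Per-variant ratios by_j/bx_j carry weights bx_j^2/sy_j^2 (the inverse
    variance of the ratio under the first-order delta approximation).  The
    bootstrap redraws bx*_j ~ N(bx_j, sx_j) and by*_j ~ N(by_j, sy_j) and
    recomputes the estimate; the SE is the standard deviation across
    resamples.
    """
    bx, sx, by, sy = _unpack(data)
    keep = bx != 0
    dropped = int(np.sum(~keep))
    bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
    J = bx.size
    if J < 3:
        raise ValueError(f"weighted median needs at least 3 usable variants, got {J}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")

    ratios = by / bx
    weights = (bx / sy) ** 2
    theta = _weighted_median(ratios, weights)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, J))
    bys = rng.normal(by, sy, size=(n_boot, J))
    bxs[bxs == 0.0] = np.finfo(float).tiny  # ratio must stay defined
    est = np.empty(n_boot)
    rb = bys / bxs
    wb = (bxs / sy) ** 2
    for i in range(n_boot):
        est[i] = _weighted_median(rb[i], wb[i])
    se = float(np.std(est, ddof=1))
    return MREstimate(
        method="weighted-median",
        theta=theta,
        se=se,
        n_variants=J,
    )
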