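"""Heterogeneity, influence, enrichment and stability diagnostics.

These surround the MR estimates: Cochran's Q tests whether the per-variant
outcome associations scatter around the fitted slope more than their
standard errors allow; Cook's distances flag variants that single-handedly
move the fit; the leave-subset-out analysis checks how stable the sign of
the causal estimate is to random removal of a fraction of instruments; and
the QQ / counting utilities quantify whether a set of variants is more
associated with an outcome than chance predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import pvalues
from .summary_data import HarmonizedSet
from .univariable import MREstimate, ivw, egger, weighted_median

__all__ = [
    "cochran_q",
    "cooks_distances",
    "leave_subset_out",
    "qq_statistics",
    "count_significant",
    "bonferroni_threshold",
]


def cochran_q(data, theta: float) -> tuple[float, int, float]:
    """Cochran's heterogeneity statistic around slope ``theta``.

    Q = sum_j sy_j^-2 (by_j - theta*bx_j)^2, chi-square with J-1 df under
    homogeneity (theta estimated).  Returns (Q, df, upper-tail p).
    """
    if isinstance(data, HarmonizedSet):
        bx, sx, by, sy = data.single()
    else:
        bx, sx, by, sy = (np.asarray(v, float) for v in data)
    J = bx.size
    if J < 2:
        raise ValueError("Cochran's Q needs at least 2 variants")
    q = float(np.sum(sy ** -2.0 * (by - theta * bx) ** 2))
    df = J - 1
    return q, df, float(stats.chi2.sf(q, df))


def cooks_distances(
    data, model: str = "ivw", threshold: float = 0.15
) -> tuple[np.ndarray, list[int]]:
    """Cook's distances from the weighted MR regression.

    ``model="ivw"`` uses the zero-intercept weighted regression (1 fitted
    parameter); ``"egger"`` the free-intercept regression (2 parameters,
    after exposure-increasing orientation).  Standard definition on the
    whitened regression: D_j = e_j^2 h_j / (k s^2 (1-h_j)^2) with hat
    leverage h_j, residual e_j and s^2 the weighted residual mean square.
    Returns the distances and the indices exceeding ``threshold`` (0.15 is
    the conventional screen used here).
    """
    if isinstance(data, HarmonizedSet):
        bx, sx, by, sy = data.single()
    else:
        bx, sx, by, sy = (np.asarray(v, float) for v in data)
    if model == "ivw":
        X = (bx / sy)[:, None]
    elif model == "egger":
        flip = np.where(bx < 0, -1.0, 1.0)
        X = np.column_stack([1.0 / sy, flip * bx / sy])
        by = flip * by
    else:
        raise ValueError(f"model must be 'ivw' or 'egger', got {model!r}")
    y = by / sy
    J, k = X.shape
    if J <= k:
        raise ValueError("need more variants than regression parameters")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    s2 = float(resid @ resid) / (J - k)
    if s2 == 0.0:
        d = np.zeros(J)
    else:
        d = resid ** 2 * h / (k * s2 * (1.0 - h) ** 2)
    flagged = [int(i) for i in np.flatnonzero(d > threshold)]
    return d, flagged


@dataclass
class LeaveSubsetResult:
    proportion_positive: float
    estimates: np.ndarray
    n_removed: int

    @property
    def summary(self) -> dict:
        return {
            "proportion_positive": self.proportion_positive,
            "n_iterations": int(self.estimates.size),
            "n_removed": self.n_removed,
            "median_estimate": float(np.median(self.estimates)),
        }


def leave_subset_out(
    data: HarmonizedSet,
    fraction: float = 0.3,
    n_iterations: int = 10_000,
    seed: int | np.random.Generator = 0,
    estimator: str | Callable = "ivw",
) -> LeaveSubsetResult:
    """Remove ``round(fraction*J)`` variants at random and re-estimate.

    Returns the share of iterations with a positive causal estimate and the
    full estimate distribution.  ``estimator`` may be ``"ivw"``, ``"egger"``,
    ``"weighted-median"`` or any callable mapping a HarmonizedSet to an
    :class:`MREstimate`.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    est_fn: Callable
    if estimator == "ivw":
        est_fn = ivw
    elif estimator == "egger":
        est_fn = egger
    elif estimator == "weighted-median":
        est_fn = weighted_median
    elif callable(estimator):
        est_fn = estimator
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    J = data.n_variants
    n_remove = int(round(fraction * J))
    estimates = np.empty(n_iterations)
    idx_all = np.arange(J)
    for it in range(n_iterations):
        if n_remove:
            removed = rng.choice(J, size=n_remove, replace=False)
            keep = np.setdiff1d(idx_all, removed, assume_unique=True)
        else:
            keep = idx_all
        estimates[it] = est_fn(data.subset(keep)).theta
    return LeaveSubsetResult(
        proportion_positive=float(np.mean(estimates > 0)),
        estimates=estimates,
        n_removed=n_remove,
    )


def qq_statistics(
    log10_pvals: Sequence[float], plotting_position: str = "half"
) -> pd.DataFrame:
    """Observed vs expected chi-square(1) statistics for a QQ plot.

    Observed statistics are z^2 from the two-sided p-values, sorted
    ascending; expected are chi-square(1) quantiles at rank (j-0.5)/n
    (``plotting_position="half"``, default) or j/(n+1) (``"weibull"``).
    """
    lp = np.asarray(log10_pvals, dtype=float)
    if np.any(lp > 0):
        raise ValueError("p-values must be <= 1")
    z = pvalues.z_from_log10p(lp)
    observed = np.sort(np.asarray(z) ** 2)
    n = observed.size
    j = np.arange(1, n + 1)
    if plotting_position == "half":
        ranks = (j - 0.5) / n
    elif plotting_position == "weibull":
        ranks = j / (n + 1.0)
    else:
        raise ValueError(f"unknown plotting position {plotting_position!r}")
    expected = stats.chi2.ppf(ranks, df=1)
    return pd.DataFrame({"expected": expected, "observed": observed})


def count_significant(
    log10_pvals: Sequence[float], thresholds: Sequence[float]
) -> dict[float, int]:
    """Count of p-values strictly below each threshold (log-space compare)."""
    lp = np.asarray(log10_pvals, dtype=float)
    out = {}
    for thr in thresholds:
        if not 0.0 < thr <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {thr}")
        out[thr] = int(np.sum(lp < math.log10(thr)))
    return out


def bonferroni_threshold(family_alpha: float, n_tests: int) -> float:
    """Per-test threshold controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests
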