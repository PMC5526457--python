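"""Reconstruct beta-coefficients and standard errors from p-values and MAF.

Some disease consortia publish per-variant p-values and directions of
association but not beta-coefficients or standard errors.  Under the
asymptotics of per-allele logistic regression with a common sample size, the
standard error of the log-odds beta is proportional to 1/sqrt(maf*(1-maf)):

    se_j = c / sqrt(maf_j * (1 - maf_j))

The proportionality constant c is calibrated as the average of
se*sqrt(maf*(1-maf)) over a reference set of variants whose betas and SEs
are published (typically the genome-wide significant hits).  Each remaining
variant's beta is then the calibrated SE times the signed z-score implied by
its published p-value and direction.  A split-half exercise — calibrate on
half the reference variants, reconstruct the other half, correlate with the
published betas — quantifies how well the equal-sample-size assumption holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import pvalues

__all__ = [
    "CalibrationConstant",
    "DirectionalPValue",
    "z_from_p",
    "fit_constant",
    "reconstruct",
    "split_half_validate",
]


@dataclass(frozen=True)
class CalibrationConstant:
    """Average of se*sqrt(maf*(1-maf)) over the calibration variants."""

    c: float
    n_calibration: int

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("calibration constant must be positive")
        if self.n_calibration < 2:
            raise ValueError("need at least 2 calibration variants")


@dataclass(frozen=True)
class DirectionalPValue:
    """Published two-sided p-value, association direction and MAF."""

    variant_id: str
    log10_p: float
    direction: int
    maf: float

    def __post_init__(self):
        if self.log10_p > 0:
            raise ValueError("p-value above 1")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


def z_from_p(p, direction=1):
    """Signed z-score from a two-sided p-value (float or log10 via helper).

    |z| is the upper-tail normal quantile at p/2, computed in log space so
    p-values such as 1e-300 convert without loss; the sign is ``direction``.
    """
    log10p = pvalues.log10_from_p(float(p))
    return pvalues.z_from_log10p(log10p, direction)


def fit_constant(calibration: Iterable[tuple[float, float]]) -> CalibrationConstant:
    """Calibrate c = mean of se*sqrt(maf*(1-maf)) over (se, maf) pairs."""
    pairs = list(calibration)
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration variants")
    vals = []
    for se, maf in pairs:
        if se <= 0:
            raise ValueError(f"se must be > 0, got {se}")
        if not 0.0 < maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {maf}")
        vals.append(se * np.sqrt(maf * (1.0 - maf)))
    return CalibrationConstant(c=float(np.mean(vals)), n_calibration=len(pairs))


def reconstruct(
    pvals: Sequence[DirectionalPValue], constant: CalibrationConstant
) -> tuple[list[tuple[str, float, float]], list[tuple[str, str]]]:
    """Per variant: se = c/sqrt(maf(1-maf)); beta = se * z(p, direction).

    Returns ``([(variant_id, beta, se), ...], skipped)`` where ``skipped``
    lists variants without a usable MAF.
    """
    out: list[tuple[str, float, float]] = []
    skipped: list[tuple[str, str]] = []
    for rec in pvals:
        if rec.maf is None or not np.isfinite(rec.maf):
            skipped.append((rec.variant_id, "missing maf"))
            continue
        se = constant.c / np.sqrt(rec.maf * (1.0 - rec.maf))
        z = pvalues.z_from_log10p(rec.log10_p, rec.direction)
        out.append((rec.variant_id, float(se * z), float(se)))
    return out, skipped


@dataclass
class SplitHalfResult:
    correlations: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.correlations))

    @property
    def summary(self) -> dict:
        q = np.quantile(self.correlations, [0.025, 0.5, 0.975])
        return {
            "n_iterations": int(self.correlations.size),
            "mean": self.mean,
            "median": float(q[1]),
            "q2.5": float(q[0]),
            "q97.5": float(q[2]),
        }


def split_half_validate(
    known: Sequence[tuple[str, float, float, float, float, int]],
    n_iterations: int = 100,
    seed: int | np.random.Generator = 0,
) -> SplitHalfResult:
    """Repeatedly calibrate on a random half, reconstruct the other half.

    ``known`` rows are ``(variant_id, beta, se, maf, log10_p, direction)``.
    Each iteration splits the variants at random into two (near-)equal halves,
    fits the constant on half A, reconstructs half B's betas from (p,
    direction, maf), and records the Pearson correlation between the
    reconstructed and published betas of half B.
    """
    rows = list(known)
    n = len(rows)
    if n < 4:
        raise ValueError("need at least 4 variants (2 per half)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = n // 2
    corrs = np.empty(n_iterations)
    for it in range(n_iterations):
        perm = rng.permutation(n)
        idx_a, idx_b = perm[:half], perm[half:]
        const = fit_constant([(rows[i][2], rows[i][3]) for i in idx_a])
        pv = [
            DirectionalPValue(rows[i][0], rows[i][4], rows[i][5], rows[i][3])
            for i in idx_b
        ]
        rec, _ = reconstruct(pv, const)
        betas_hat = np.array([b for _, b, _ in rec])
        betas_true = np.array([rows[i][1] for i in idx_b])
        corrs[it] = np.corrcoef(betas_hat, betas_true)[0, 1]
    return SplitHalfResult(correlations=corrs)
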