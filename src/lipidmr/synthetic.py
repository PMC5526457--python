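"""Synthetic two-sample summary statistics with known ground truth.

The generator emulates the summary-data regime the estimators consume: per
variant j, a minor-allele frequency, a true per-allele effect gamma_jk on
each exposure, and sampling noise with the GWAS asymptotic standard error
1/sqrt(2*maf*(1-maf)*n).  The outcome model is

    by_j ~ Normal( sum_k theta_k * gamma_jk + alpha_j , se_y_j )

with alpha_j a per-variant pleiotropic effect drawn from a configurable law
(none, balanced around zero, or directional with non-zero mean), optionally
correlated with instrument strength to violate the InSIDE assumption.
Exposure and outcome noise are independent (the two-sample structure).
Binary-outcome betas are generated directly on the log-odds scale under the
normal approximation; no individual-level genotypes are simulated.

Defaults mirror the study conditions of a large lipid -> disease analysis:
exposure consortium n = 188577, outcome consortium n = 33526, J = 86
instruments, maf ~ U(0.1, 0.4), per-variant exposure effects |N(0, 0.05)|
in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import pvalues
from .summary_data import AssociationTable, VariantAssociation
from .gene_region import LDMatrix

__all__ = ["PleiotropyLaw", "SyntheticTruth", "generate_two_sample", "generate_region"]

# ordered allele pairs excluding palindromic (A/T, C/G) combinations
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class PleiotropyLaw:
    """Distribution of per-variant direct (pleiotropic) outcome effects.

    ``fraction`` < 1 plants pleiotropy in a random subset of variants only
    (the "some instruments invalid" regime the weighted median is built for).
    """

    kind: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0
    fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in {"none", "balanced", "directional"}:
            raise ValueError(f"unknown pleiotropy law {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0.0:
            raise ValueError("balanced pleiotropy must have mean 0")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")

    @classmethod
    def none(cls) -> "PleiotropyLaw":
        return cls("none")

    @classmethod
    def balanced(cls, sd: float = 0.005, fraction: float = 1.0) -> "PleiotropyLaw":
        return cls("balanced", 0.0, sd, fraction)

    @classmethod
    def directional(
        cls, mean: float = 0.03, sd: float = 0.0, fraction: float = 1.0
    ) -> "PleiotropyLaw":
        return cls("directional", mean, sd, fraction)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters kept alongside generated data for recovery tests."""

    theta: tuple[float, ...] = (0.5,)
    pleiotropy: PleiotropyLaw = field(default_factory=PleiotropyLaw.none)
    inside_violation: bool = False
    inside_corr: float = 0.0
    J: int = 86
    n_exposure: int = 188_577
    n_outcome: int = 33_526
    maf_range: tuple[float, float] = (0.1, 0.4)
    gamma_sd: float = 0.05
    gamma_corr: float = 0.0
    flip_fraction: float = 0.0
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must be in [0, 1]")

    @property
    def K(self) -> int:
        return len(self.theta)


def _draw_gamma(truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    """True exposure effects, |N(0, gamma_sd)|, optionally cross-correlated."""
    J, K = truth.J, truth.K
    if K == 1 or truth.gamma_corr == 0.0:
        raw = rng.normal(0.0, truth.gamma_sd, size=(J, K))
    else:
        c = truth.gamma_corr
        corr = np.full((K, K), c) + (1.0 - c) * np.eye(K)
        L = np.linalg.cholesky(corr)
        raw = rng.normal(size=(J, K)) @ L.T * truth.gamma_sd
    return np.abs(raw)


def _draw_alpha(
    truth: SyntheticTruth, gamma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    law = truth.pleiotropy
    if law.kind == "none":
        return np.zeros(truth.J)
    eps = rng.normal(size=truth.J)
    if truth.inside_violation and truth.inside_corr != 0.0:
        g = gamma[:, 0]
        gs = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
        r = truth.inside_corr
        eps = r * gs + np.sqrt(1.0 - r ** 2) * eps
    alpha = law.mean + law.sd * eps
    if law.fraction < 1.0:
        alpha = np.where(rng.random(truth.J) < law.fraction, alpha, 0.0)
    return alpha


def _build_table(
    trait_name: str,
    trait_scale: str,
    ids: list[str],
    alleles: list[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    flip_mask: np.ndarray,
) -> AssociationTable:
    records = []
    for j, vid in enumerate(ids):
        ea, oa = alleles[j]
        b, f = beta[j], eaf[j]
        if flip_mask[j]:
            ea, oa, b, f = oa, ea, -b, 1.0 - f
        z = b / se[j]
        records.append(
            VariantAssociation(
                variant_id=vid,
                effect_allele=ea,
                other_allele=oa,
                beta=float(b),
                se=float(se[j]),
                log10_p=pvalues.log10p_from_z(z),
                eaf=float(f),
                n=float(n),
            )
        )
    return AssociationTable(trait_name, trait_scale, records)


def generate_two_sample(
    truth: SyntheticTruth,
) -> tuple[list[AssociationTable], AssociationTable, SyntheticTruth]:
    """Generate exposure and outcome association tables under ``truth``.

    Returns ``(exposure_tables, outcome_table, truth)``.  With
    ``truth.noiseless`` the observed betas equal their expectations (the
    infinite-sample limit) while the reported SEs keep their finite-sample
    values, so estimator weights stay defined.
    """
    rng = np.random.default_rng(truth.seed)
    J, K = truth.J, truth.K
    ids = [f"rs{j + 1:06d}" for j in range(J)]
    maf = rng.uniform(*truth.maf_range, size=J)
    eaf = np.where(rng.random(J) < 0.5, maf, 1.0 - maf)
    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=J)]

    gamma = _draw_gamma(truth, rng)
    alpha = _draw_alpha(truth, gamma, rng)

    het = 2.0 * maf * (1.0 - maf)
    sex = 1.0 / np.sqrt(het * truth.n_exposure)
    sey = 1.0 / np.sqrt(het * truth.n_outcome)

    noise = 0.0 if truth.noiseless else 1.0
    theta = np.asarray(truth.theta, float)
    bx = gamma + noise * rng.normal(size=(J, K)) * sex[:, None]
    by = gamma @ theta + alpha + noise * rng.normal(size=J) * sey

    no_flip = np.zeros(J, dtype=bool)
    exposures = [
        _build_table(
            f"exposure_{k + 1}", "sd-units", ids, alleles, eaf,
            bx[:, k], sex, truth.n_exposure, no_flip,
        )
        for k in range(K)
    ]
    out_flip = rng.random(J) < truth.flip_fraction
    outcome = _build_table(
        "outcome", "log-odds", ids, alleles, eaf, by, sey, truth.n_outcome, out_flip
    )
    return exposures, outcome, truth


def generate_region(
    truth: SyntheticTruth, rho: np.ndarray
) -> tuple[AssociationTable, AssociationTable, LDMatrix, SyntheticTruth]:
    """Generate one gene region's correlated summary statistics.

    Observed betas get covariance diag(se) rho diag(se) on both the exposure
    and outcome side (independent draws — the two-sample structure), via a
    Cholesky factor of rho.  Returns (exposure, outcome, ld, truth).
    """
    rho = np.asarray(rho, float)
    J = truth.J
    if rho.shape != (J, J):
        raise ValueError(f"rho must be {J}x{J}")
    if truth.K != 1:
        raise ValueError("gene-region generator is single-exposure")
    try:
        L = np.linalg.cholesky(rho)
    except np.linalg.LinAlgError as err:
        raise ValueError("rho must be positive definite") from err

    rng = np.random.default_rng(truth.seed)
    ids = [f"rs{j + 1:06d}" for j in range(J)]
    maf = rng.uniform(*truth.maf_range, size=J)
    eaf = np.where(rng.random(J) < 0.5, maf, 1.0 - maf)
    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=J)]

    gamma = np.abs(rng.normal(0.0, truth.gamma_sd, size=J))
    het = 2.0 * maf * (1.0 - maf)
    sex = 1.0 / np.sqrt(het * truth.n_exposure)
    sey = 1.0 / np.sqrt(het * truth.n_outcome)

    noise = 0.0 if truth.noiseless else 1.0
    bx = gamma + noise * sex * (L @ rng.normal(size=J))
    by = truth.theta[0] * gamma + noise * sey * (L @ rng.normal(size=J))

    no_flip = np.zeros(J, dtype=bool)
    exposure = _build_table(
        "exposure_1", "sd-units", ids, alleles, eaf, bx, sex, truth.n_exposure, no_flip
    )
    outcome = _build_table(
        "outcome", "log-odds", ids, alleles, eaf, by, sey, truth.n_outcome, no_flip
    )
    return exposure, outcome, LDMatrix(ids, rho), truth
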