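"""Gene-region (drug-target proxy) analyses with correlated variants.

Variants within one gene region are in linkage disequilibrium, so the
independent-variant IVW is not valid there.  Given the region's LD
correlation matrix rho, the causal effect is estimated by generalized
weighted least squares through the origin with outcome covariance
Omega = diag(sy) rho diag(sy):

    theta = (bx' Omega^-1 bx)^-1  bx' Omega^-1 by
    se    = (bx' Omega^-1 bx)^-1/2

This is equivalent to testing a genetic risk score built from the region's
variants, weighted by their (conditional) exposure associations.  A greedy
r^2 screen selects approximately independent variants before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .summary_data import HarmonizedSet
from .univariable import MREstimate

__all__ = ["LDMatrix", "read_ld_matrix", "correlated_ivw", "screen_correlated"]

_SYM_TOL = 1e-8
_EIG_TOL = -1e-8
_RIDGE = 1e-6


@dataclass
class LDMatrix:
    """Labelled square matrix of pairwise variant correlations (r)."""

    variant_ids: list[str]
    rho: np.ndarray

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.variant_ids)
        if self.rho.shape != (n, n):
            raise ValueError(f"rho must be {n}x{n}, got {self.rho.shape}")
        if np.max(np.abs(self.rho - self.rho.T)) > _SYM_TOL:
            raise ValueError("rho is not symmetric")
        if np.max(np.abs(np.diag(self.rho) - 1.0)) > _SYM_TOL:
            raise ValueError("rho diagonal must be 1")
        if np.min(np.linalg.eigvalsh(self.rho)) < _EIG_TOL:
            raise ValueError("rho is not positive semi-definite")

    def subset(self, ids: list[str]) -> "LDMatrix":
        idx = [self.variant_ids.index(v) for v in ids]
        return LDMatrix(ids, self.rho[np.ix_(idx, idx)])


def read_ld_matrix(path) -> LDMatrix:
    """Whitespace-delimited square matrix with a header row of variant IDs."""
    df = pd.read_csv(path, sep=r"\s+")
    ids = [str(c) for c in df.columns]
    return LDMatrix(ids, df.to_numpy(dtype=float))


def correlated_ivw(
    data,
    ld: LDMatrix,
    effects: str = "fixed",
) -> MREstimate:
    """IVW causal estimate using correlated variants from one gene region.

    ``data`` is a single-exposure :class:`HarmonizedSet` (or an
    ``(bx, sx, by, sy)`` tuple with matching variant order) whose variants
    must equal ``ld.variant_ids`` in order.  Near-singular rho is ridge-
    adjusted (rho + 1e-6 I); truly singular rho raises with advice to prune.
    Exposure betas should be the conditional (joint-model) associations when
    several variants per region are used.
    """
    if isinstance(data, HarmonizedSet):
        if data.variant_ids != ld.variant_ids:
            raise ValueError("variant order mismatch between data and LD matrix")
        bx, sx, by, sy = data.single()
    else:
        bx, sx, by, sy = (np.asarray(v, float) for v in data)
    J = bx.size
    if ld.rho.shape != (J, J):
        raise ValueError("LD matrix size does not match variant count")

    rho = ld.rho
    if np.min(np.linalg.eigvalsh(rho)) < 1e-8:
        rho = rho + _RIDGE * np.eye(J)
    omega = rho * np.outer(sy, sy)
    try:
        cho = linalg.cho_factor(omega)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "LD matrix singular beyond ridge tolerance; prune correlated variants"
        ) from err
    oi_bx = linalg.cho_solve(cho, bx)
    denom = float(bx @ oi_bx)
    if denom <= 0:
        raise np.linalg.LinAlgError("all exposure betas zero: singular design")
    theta = float(oi_bx @ by) / denom
    se = denom ** -0.5
    resid = by - theta * bx
    q = float(resid @ linalg.cho_solve(cho, resid))
    df = J - 1
    phi = max(1.0, q / df) if df > 0 else 1.0
    if effects == "random":
        se *= math.sqrt(phi)
    return MREstimate(
        method=f"correlated-ivw-{effects}",
        theta=theta,
        se=se,
        n_variants=J,
        q_statistic=q,
        q_df=df,
        phi=phi,
    )


def screen_correlated(
    candidates: list[str], ld: LDMatrix, r2_max: float = 0.2
) -> list[str]:
    """Greedy selection keeping variants minimally correlated (r^2 < r2_max).

    Walks the candidates in input order and keeps a variant only if its
    squared correlation with every already-kept variant is below ``r2_max``.
    """
    if not 0.0 < r2_max < 1.0:
        raise ValueError(f"r2_max must be in (0, 1), got {r2_max}")
    pos = {v: i for i, v in enumerate(ld.variant_ids)}
    kept: list[str] = []
    for v in candidates:
        i = pos[v]
        if all(ld.rho[i, pos[k]] ** 2 < r2_max for k in kept):
            kept.append(v)
    return kept
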