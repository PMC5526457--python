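"""Multivariable Mendelian randomization: joint direct effects of K exposures.

The outcome associations by_j are regressed on the J x K matrix of exposure
associations in a single zero-intercept weighted regression (weights 1/sy^2).
Each slope is the direct effect of that exposure with the others held fixed,
so a variant may act on the outcome through any of the modelled exposures
without violating the model.  Standard errors carry the multiplicative
random-effects inflation sqrt(max(1, Q/(J-K))).

The fitted values theta_hat' bx_j are the associations the lipid model
predicts for each variant; the squared correlation between fitted and
observed outcome associations summarizes how much of the association pattern
the exposures explain.
"""

from __future__ import annotations

import math

import numpy as np

from .summary_data import HarmonizedSet
from .univariable import MREstimate

__all__ = ["mvmr_fit", "fitted_observed_r2"]


def mvmr_fit(
    data, effects: str = "random"
) -> tuple[list[MREstimate], np.ndarray]:
    """Weighted least squares of by on the exposure-beta matrix, no intercept.

    Returns one :class:`MREstimate` per exposure plus the fitted vector
    theta_hat' bx_j.  Raises on rank deficiency (naming the collinear
    columns) and when J <= K.
    """
    if isinstance(data, HarmonizedSet):
        bx, by, sy = data.bx, data.by, data.sy
        names = data.exposure_names
    else:
        bx, by, sy = data
        bx = np.atleast_2d(np.asarray(bx, float))
        if bx.shape[0] == 1 and np.asarray(by).size != 1:
            bx = bx.T
        by = np.asarray(by, float)
        sy = np.asarray(sy, float)
        names = [f"exposure_{k+1}" for k in range(bx.shape[1])]
    J, K = bx.shape
    if J <= K:
        raise ValueError(f"need more variants than exposures (J={J}, K={K})")

    sw = 1.0 / sy
    X = bx * sw[:, None]  # whitened design
    y = by * sw
    rank = np.linalg.matrix_rank(X)
    if rank < K:
        # name columns whose removal restores full rank
        collinear = [
            names[k]
            for k in range(K)
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"singular design: collinear exposure columns {collinear}"
        )
    xtx = X.T @ X
    theta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ theta
    q = float(resid @ resid)
    df = J - K
    phi = max(1.0, q / df)
    cov = np.linalg.inv(xtx)
    scale = phi if effects == "random" else 1.0
    ses = np.sqrt(scale * np.diag(cov))
    fitted = bx @ theta
    estimates = [
        MREstimate(
            method=f"mvmr-{effects}:{names[k]}",
            theta=float(theta[k]),
            se=float(ses[k]),
            n_variants=J,
            q_statistic=q,
            q_df=df,
            phi=phi,
        )
        for k in range(K)
    ]
    return estimates, fitted


def fitted_observed_r2(observed, fitted, weights=None) -> float:
    """Squared Pearson correlation of observed vs fitted associations, in %.

    ``weights`` switches to the weighted correlation (weighted covariance
    over weighted variances); the unweighted version is the primary report.
    Raises ``ValueError`` when either vector has zero variance.
    """
    obs = np.asarray(observed, float)
    fit = np.asarray(fitted, float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValueError("observed and fitted must be equal-length, size >= 2")
    if weights is None:
        w = np.ones_like(obs)
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    mo, mf = np.sum(w * obs), np.sum(w * fit)
    vo = np.sum(w * (obs - mo) ** 2)
    vf = np.sum(w * (fit - mf) ** 2)
    if vo == 0.0 or vf == 0.0:
        raise ValueError("zero variance: R^2 undefined")
    cov = np.sum(w * (obs - mo) * (fit - mf))
    return float(100.0 * cov ** 2 / (vo * vf))
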