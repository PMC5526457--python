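"""Replicated simulation experiments over the estimators.

These functions are the computational core of the analysis drivers: each one
generates synthetic two-sample datasets with known truth through
:mod:`lipidmr.synthetic`, pushes them through the real harmonization and
estimation path, and summarizes recovery, calibration or robustness across
replicates.  Problem sizes default to desk scale (hundreds of replicates of
an 86-instrument analysis) so a full run completes in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from . import reconstruction, univariable
from .diagnostics import cochran_q
from .summary_data import AssociationTable, harmonize, select_instruments
from .synthetic import PleiotropyLaw, SyntheticTruth, generate_two_sample

GENOME_WIDE_P = 5e-8

__all__ = [
    "recovery_experiment",
    "null_calibration",
    "pvalue_uniformity",
    "reconstruction_roundtrip",
    "robustness_experiment",
]


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    # keep derived seeds below 2**31 so they survive any int32 consumer
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31 - 1)


def _harmonized_instruments(exposures, outcome, select_threshold):
    """Harmonize after the genome-wide instrument screen the analysis uses.

    Published instrument sets contain only genome-wide significant variants;
    admitting sub-significant ones would let near-null instruments flip sign
    under the exposure-increasing orientation and break the InSIDE premise.
    """
    exp = exposures[0]
    if select_threshold is not None:
        keep = set(select_instruments(exp, select_threshold))
        exp = AssociationTable(
            exp.trait_name, exp.trait_scale,
            [r for r in exp.records if r.variant_id in keep],
        )
    return harmonize([exp] + list(exposures[1:]), outcome)


def _fit_all(hs, n_boot: int, seed: int, methods: tuple[str, ...]):
    out = {}
    if "ivw" in methods:
        out["ivw"] = univariable.ivw(hs, effects="random")
    if "egger" in methods:
        out["egger"] = univariable.egger(hs)
    if "weighted-median" in methods:
        out["weighted-median"] = univariable.weighted_median(
            hs, n_boot=n_boot, seed=seed
        )
    return out


def recovery_experiment(
    truth: SyntheticTruth | None = None,
    n_reps: int = 500,
    seed: int = 0,
    n_boot: int = 500,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted-median"),
    select_threshold: float | None = GENOME_WIDE_P,
) -> dict:
    """Bias and 95% CI coverage of each estimator over ``n_reps`` datasets.

    Default truth: theta = 0.5, 86 instruments, no pleiotropy — the regime
    where all three estimators are consistent.  Returns per-method mean
    estimate, bias, Monte-Carlo SE of the mean, and coverage, plus the mean
    MR-Egger intercept when the Egger method runs.
    """
    if truth is None:
        truth = SyntheticTruth(theta=(0.5,))
    theta0 = truth.theta[0]
    seeds = _spawn_seeds(seed, n_reps)
    est = {m: np.empty(n_reps) for m in methods}
    cover = {m: np.empty(n_reps, dtype=bool) for m in methods}
    icept = np.empty(n_reps) if "egger" in methods else None
    for r in range(n_reps):
        t = replace(truth, seed=int(seeds[r]))
        exposures, outcome, _ = generate_two_sample(t)
        hs = _harmonized_instruments(exposures, outcome, select_threshold)
        fits = _fit_all(hs, n_boot, int(seeds[r]) ^ 0x5EED, methods)
        for m, fit in fits.items():
            est[m][r] = fit.theta
            cover[m][r] = fit.ci_low <= theta0 <= fit.ci_high
        if icept is not None:
            icept[r] = fits["egger"].intercept
    result = {"truth_theta": theta0, "n_reps": n_reps}
    for m in methods:
        result[m] = {
            "mean_estimate": float(est[m].mean()),
            "bias": float(est[m].mean() - theta0),
            "mc_se": float(est[m].std(ddof=1) / np.sqrt(n_reps)),
            "coverage": float(cover[m].mean()),
        }
    if icept is not None:
        result["egger_intercept"] = {
            "mean": float(icept.mean()),
            "mc_se": float(icept.std(ddof=1) / np.sqrt(n_reps)),
        }
    return result


def null_calibration(
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pleiotropy: PleiotropyLaw | None = None,
    select_threshold: float | None = GENOME_WIDE_P,
) -> dict:
    """Type-I error of the random-effects IVW test and Cochran-Q rejection.

    The IVW type-I error is evaluated under theta = 0 with balanced
    pleiotropy (heterogeneity present, no directional signal); the Q
    rejection rate under theta = 0 with no pleiotropy (true homogeneity),
    where Q is exactly chi-square distributed.
    """
    if pleiotropy is None:
        pleiotropy = PleiotropyLaw.balanced()
    seeds = _spawn_seeds(seed, 2 * n_reps)
    reject_ivw = np.empty(n_reps, dtype=bool)
    truth_b = SyntheticTruth(theta=(0.0,), pleiotropy=pleiotropy)
    for r in range(n_reps):
        exposures, outcome, _ = generate_two_sample(
            replace(truth_b, seed=int(seeds[r]))
        )
        hs = _harmonized_instruments(exposures, outcome, select_threshold)
        reject_ivw[r] = univariable.ivw(hs).p < alpha

    reject_q = np.empty(n_reps, dtype=bool)
    q_over_df = np.empty(n_reps)
    truth_h = SyntheticTruth(theta=(0.0,))
    for r in range(n_reps):
        exposures, outcome, _ = generate_two_sample(
            replace(truth_h, seed=int(seeds[n_reps + r]))
        )
        hs = _harmonized_instruments(exposures, outcome, select_threshold)
        fit = univariable.ivw(hs)
        q, df, p = cochran_q(hs, fit.theta)
        reject_q[r] = p < alpha
        q_over_df[r] = q / df
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "ivw_type1_error": float(reject_ivw.mean()),
        "q_rejection_rate": float(reject_q.mean()),
        "mean_q_over_df": float(q_over_df.mean()),
    }


def pvalue_uniformity(n_variants: int = 10_000, seed: int = 0) -> dict:
    """KS test of generated exposure p-values against U(0,1) under the null.

    With all true exposure effects set to zero the Wald p-values of the
    generated exposure associations must be uniform.
    """
    truth = SyntheticTruth(
        theta=(0.0,), J=n_variants, gamma_sd=0.0, seed=seed
    )
    exposures, _, _ = generate_two_sample(truth)
    pvals = np.array([10.0 ** r.log10_p for r in exposures[0].records])
    ks = stats.kstest(pvals, "uniform")
    return {
        "n_variants": n_variants,
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


def reconstruction_roundtrip(
    n_variants: int = 34,
    c0: float = 0.012,
    seed: int = 0,
    n_iterations: int = 100,
) -> dict:
    """Self-inverse check of beta/SE reconstruction under the exact SE model.

    Simulates variants whose SEs follow se = c0/sqrt(maf(1-maf)) exactly,
    converts the betas to (p, direction, maf), reconstructs, and reports the
    correlation and maximum absolute error against the originals, plus the
    split-half validation distribution on the same data.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, size=n_variants)
    se = c0 / np.sqrt(maf * (1.0 - maf))
    # z capped so the p -> z inversion stays within its 1e-10 regime
    z = rng.uniform(-30.0, 30.0, size=n_variants)
    beta = z * se
    from . import pvalues as _pv

    log10p = _pv.log10p_from_z(z)
    direction = np.where(beta >= 0, 1, -1)

    const = reconstruction.fit_constant(list(zip(se, maf)))
    pv = [
        reconstruction.DirectionalPValue(f"v{j}", float(log10p[j]), int(direction[j]), float(maf[j]))
        for j in range(n_variants)
    ]
    rec, skipped = reconstruction.reconstruct(pv, const)
    beta_hat = np.array([b for _, b, _ in rec])
    corr = float(np.corrcoef(beta_hat, beta)[0, 1])
    max_err = float(np.max(np.abs(beta_hat - beta)))

    known = [
        (f"v{j}", float(beta[j]), float(se[j]), float(maf[j]), float(log10p[j]), int(direction[j]))
        for j in range(n_variants)
    ]
    sh = reconstruction.split_half_validate(known, n_iterations=n_iterations, seed=seed)
    return {
        "n_variants": n_variants,
        "correlation": corr,
        "max_abs_beta_error": max_err,
        "split_half_mean": sh.mean,
        "split_half_min": float(sh.correlations.min()),
    }


def robustness_experiment(
    n_reps: int = 200,
    seed: int = 0,
    invalid_fraction: float = 0.3,
    invalid_effect: float = 0.05,
    theta: float = 0.5,
    select_threshold: float | None = GENOME_WIDE_P,
    noiseless: bool = False,
) -> dict:
    """Weighted median vs IVW when a minority of instruments is invalid.

    ``invalid_fraction`` of variants receive a large positive pleiotropic
    effect; the weighted median should stay near the truth (majority of
    weight still valid) while the IVW mean is displaced in the planted
    direction.
    """
    law = PleiotropyLaw.directional(mean=invalid_effect, fraction=invalid_fraction)
    truth = SyntheticTruth(theta=(theta,), pleiotropy=law, noiseless=noiseless)
    seeds = _spawn_seeds(seed, n_reps)
    wm = np.empty(n_reps)
    iv = np.empty(n_reps)
    for r in range(n_reps):
        exposures, outcome, _ = generate_two_sample(replace(truth, seed=int(seeds[r])))
        hs = _harmonized_instruments(exposures, outcome, select_threshold)
        iv[r] = univariable.ivw(hs).theta
        wm[r] = univariable.weighted_median(
            hs, n_boot=100, seed=int(seeds[r]) ^ 0x5EED
        ).theta
    return {
        "n_reps": n_reps,
        "truth_theta": theta,
        "weighted_median_mean": float(wm.mean()),
        "weighted_median_abs_bias": float(abs(wm.mean() - theta)),
        "ivw_mean": float(iv.mean()),
        "ivw_bias": float(iv.mean() - theta),
    }
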