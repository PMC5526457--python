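# Methods

## Model and estimators

For variant j = 1..J, let bxⱼ (SE sxⱼ) be its per-allele association with an
exposure in SD units and byⱼ (SE syⱼ) its association with a binary outcome
in log odds, estimated in non-overlapping samples (two-sample design). Under
the instrumental-variable assumptions each variant identifies the same
causal slope θ = byⱼ/bxⱼ (log odds per SD of exposure).

**IVW.** Zero-intercept weighted regression of by on bx with weights
wⱼ = syⱼ⁻²: θ̂ = Σwⱼbxⱼbyⱼ / Σwⱼbxⱼ², se_fixed = (Σwⱼbxⱼ²)^{−1/2}.
Heterogeneity is absorbed multiplicatively: with
Q = Σwⱼ(byⱼ − θ̂bxⱼ)² and φ = max(1, Q/(J−1)), the random-effects SE is
se_fixed·√φ. The floor at 1 means standard errors are never shrunk below
the fixed-effect value when the data underdisperse. Exposure-side
uncertainty is ignored in the weights (the convention of summary-data MR);
consequently the Wald ratio SE is sy/|bx| (first-order delta), and IVW with
J = 1 reduces to it exactly.

**MR-Egger.** Every row is first oriented to the exposure-increasing allele
(bx, by sign-flipped together where bx < 0 — an allele relabelling), then by
is regressed on bx with a free intercept, same weights, dispersion
φ = max(1, Q/(J−2)). The slope is the causal estimate, consistent when
pleiotropic effects are independent of instrument strength (InSIDE); the
intercept estimates average directional pleiotropy and its two-sided normal
p-value is the pleiotropy test.

**Weighted median.** Ratios θⱼ = byⱼ/bxⱼ carry weights w′ⱼ = bxⱼ²/syⱼ²
(the inverse first-order variance of the ratio), normalized to sum 1. With
ratios sorted ascending and Sₖ the cumulative weight, rank
pₖ = Sₖ − w′ₖ/2; the estimate interpolates θ linearly across the two ranks
bracketing 0.5 (ties in ratios broken by stable sort, i.e. input order).
The SE is the standard deviation of the estimate over n_boot = 1000
parametric resamples bxⱼ* ~ N(bxⱼ, sxⱼ), byⱼ* ~ N(byⱼ, syⱼ); the bootstrap
seed is a required input. The estimator is consistent when ≥ 50% of the
weight comes from valid instruments.

**Multivariable MR.** by regressed jointly on the J×K matrix of exposure
associations, no intercept, weights syⱼ⁻², φ = max(1, Q/(J−K)). Each slope
is a direct effect holding the other exposures fixed. The fitted values
θ̂ᵀbxⱼ are compared with the observed byⱼ by squared Pearson correlation
(reported in %); the unweighted R² is primary and the syⱼ⁻²-weighted
variant is reported alongside, since either convention is defensible.

**Correlated variants (gene regions).** With LD correlation matrix ρ,
generalized least squares through the origin: Ω = diag(sy)·ρ·diag(sy),
θ̂ = (bxᵀΩ⁻¹bx)⁻¹bxᵀΩ⁻¹by, se = (bxᵀΩ⁻¹bx)^{−1/2} — equivalent to testing
a genetic risk score weighted by the (conditional) exposure associations.
Near-singular ρ (smallest eigenvalue < 1e-8) gets a ridge ρ + 1e-6·I;
matrices singular beyond that raise with advice to prune. The greedy screen
keeps a candidate only if r² < 0.2 against every already-kept variant, in
input order.

All confidence intervals use normal quantiles (the summary-data MR
convention) and all tests are two-sided.

## Beta/SE reconstruction

Some disease consortia publish per-variant p-values and effect directions
but not betas/SEs. Under per-allele logistic regression with a common
sample size, se ≈ c/√(MAF(1−MAF)). The constant is calibrated as the mean
of se·√(maf(1−maf)) over a reference set with published betas (mean, not
median, matching "average" calibration); then seⱼ = c/√(mafⱼ(1−mafⱼ)) and
βⱼ = seⱼ·zⱼ with zⱼ the signed normal quantile of the two-sided p-value.
Split-half validation repeatedly calibrates on a random half and correlates
reconstructed betas of the other half with their published values; the
number of splits is configurable and the whole distribution is reported,
since a single random split is noisy. Under the exact SE model the
procedure is self-inverse to < 1e-10 for |z| < 37.

P-values are carried as log10 values throughout: decimal strings are parsed
mantissa/exponent so `8e-373` never touches a denormal double, threshold
comparisons run in log space, and the p ↔ z conversions use
`scipy.special.ndtri_exp` / `log_ndtr`.

## Diagnostics

Cochran's Q at the IVW estimate (df = J−1, upper-tail chi-square) tests
whether outcome associations scatter more than their SEs allow. Cook's
distances come from the whitened weighted regression,
Dⱼ = eⱼ²hⱼ/(k·s²·(1−hⱼ)²) with hat leverage hⱼ and s² the weighted
residual mean square — the standard definition, equal to the
leave-one-out form Σᵢwᵢ(fitᵢ − fitᵢ₍₋ⱼ₎)²/(k·s²); the influence screen
flags Dⱼ > 0.15 by default. The leave-subset-out analysis removes
round(f·J) variants at random (default f = 0.30), re-estimates, and reports
the share of iterations with a positive estimate; the default 10,000
iterations give a Monte-Carlo SE below 0.5 percentage points on that share
(the analysis scales to millions of iterations by argument). QQ plots use
observed χ² = z² from the two-sided p-values against χ²(1) quantiles at
plotting positions (j−0.5)/n (j/(n+1) by option). Significance counting
uses strict inequality p < threshold, and the Bonferroni helper is α/n.

## Synthetic data generator

Per variant: maf ~ U(0.1, 0.4); true exposure effect γⱼ ~ |N(0, 0.05)| SD
units (instruments vary in strength; optionally correlated across K
exposures); sampling SEs follow the GWAS asymptotic 1/√(2·maf(1−maf)·n)
with n_exposure = 188,577 and n_outcome = 33,526 by default — the sample
sizes of the large lipid and disease consortia this design emulates; J = 86
candidate variants by default, the size of an HDL instrument set. Observed
bxⱼ ~ N(γⱼ, sxⱼ); byⱼ ~ N(θᵀγⱼ + αⱼ, syⱼ) with exposure and outcome noise
independent (two-sample structure). Pleiotropy αⱼ is none, balanced
(mean 0, default sd 0.005 — the order of the outcome-beta sampling SE, so
heterogeneity is visible but not dominant), or directional (default mean
0.03); a `fraction` < 1 plants it in a random subset (the invalid-instrument
regime), and an InSIDE-violation flag correlates αⱼ with γⱼ. Binary-outcome
betas are generated directly on the log-odds scale under the normal
approximation; no individual-level genotypes, LD panels, or winner's-curse
selection are simulated. Alleles are drawn from non-palindromic pairs, and
a configurable fraction of outcome rows is written allele-flipped to
exercise harmonization. Identical truth + seed reproduces byte-identical
tables.

Because replicated experiments analyze these data the way a real analysis
would, instruments are screened at genome-wide significance (p < 5×10⁻⁸ on
the exposure) before estimation: of 86 generated candidates, typically
~57 pass. Without the screen, near-null instruments whose observed bx is
negative by chance get sign-flipped by the Egger orientation, which turns
directional pleiotropy into strength-correlated pleiotropy and biases the
Egger slope — an artifact of admitting instruments no real analysis would
admit, not a property of the estimator.

What passing tests show about real data, and what they do not: the
generator reproduces the sampling structure and pleiotropy regimes the
estimators are built for, so recovery/calibration results validate the
estimators and the pipeline plumbing. They do not speak to strand
ambiguity resolution quality, LD between candidate variants across regions,
winner's curse in instrument discovery, or case-control SE inflation
(real binary-trait SEs are roughly twice the 1/√(2·maf(1−maf)·n) idealization
at ~50% case fraction).

## Harmonization conventions

Tables are aligned to the first exposure's effect allele; swapped alleles
negate betas (and complement EAF) in every column simultaneously, so
estimators are invariant to per-variant orientation. Variants missing from
any table, or with irreconcilable allele pairs, are dropped with explicit
reasons — never silently kept or deduplicated; harmonized + dropped counts
always add to the intersection size. Palindromic variants (A/T, C/G) are
ambiguous to strand: the default policy drops them when maf > 0.42 and
aligns the rest by effect-allele-frequency agreement; `drop` and `keep` are
available where the ancestries make a different trade-off appropriate.

## Problem sizes and numerical choices

Replicated studies default to desk scale: 500 replicates for
bias/coverage, 1000 for test calibration, 200 for robustness, 10,000
leave-out iterations, bootstrap 500–1000 — sizes chosen so the full
validation suite runs in minutes on one CPU while Monte-Carlo SEs stay well
inside the tolerances asserted. Seeds derive from a single
`numpy.random.SeedSequence` and stay below 2³¹.

## Known limitations

- The weighted median's robustness to a minority of invalid instruments is
  an asymptotic property: at consortium-scale outcome noise (sy/γ ~ 0.1–0.4
  per ratio), planting large positive pleiotropy in 30% of instruments
  shifts the 50%-weight point to roughly the 71st weighted percentile of the
  valid ratio distribution, displacing the estimate by ~0.06–0.09 on a true
  slope of 0.5 regardless of how large the planted effect is. The
  displacement vanishes in the noiseless limit (verified by test); at
  realistic noise the estimator is directionally robust (far less displaced
  than IVW) but not within 0.05 of the truth.
- Wald/IVW weights ignore exposure-side uncertainty (no second-order delta
  option); with genome-wide significant instruments the attenuation this
  causes is below 1%.
- Reconstruction assumes a common sample size across variants; per-variant
  n adjustment is out of scope, as are reconstructions from confidence
  intervals or allele counts.
- No MR-PRESSO, mode-based estimators, Steiger filtering, conditional
  F-statistics, colocalization, or LD estimation from genotype panels.
- Gene-region analyses require user-supplied conditional exposure betas and
  an LD matrix; the package records, but cannot verify, which beta
  convention (marginal vs conditional) the user declared.
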