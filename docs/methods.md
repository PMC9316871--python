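# Methods

This note records the models, formulas, parameter choices and known
limitations behind `teacqsar`, in the order the pipeline uses them.

## Assay model

The DPPH signal is modeled as the **peak-area ratio** sample/blank: 1 for
no scavenging, 0 for complete decolorization. The TROLOX calibration is an
ordinary least-squares line `signal = a·conc + b` (slope expected negative,
intercept near 1 for a ratio-type signal); TEAC inverts it,
`TEAC = (signal − b)/a`. Two numerical guards apply: inversions below zero
clamp to 0 mM with a flag (TEAC is a concentration and cannot be negative;
tiny negative inversions arise from noise around the blank level), and
inversions above the calibrated maximum are returned but flagged as
extrapolation. Replicate dispersion uses the sample standard deviation
(n−1), the analytical-chemistry convention for RSD.

Open point: whether the original assay's printed calibration response is a
peak-area ratio or a normalized absolute area is not documented; the
ratio reading is adopted because it makes the intercept ≈ 1 natural.

## Activity bands

TEAC values are interpreted in three bands: low < 0.100 mM,
0.100 ≤ mid ≤ 0.200 mM, high > 0.200 mM. The mid band is closed on both
ends; this is the only boundary convention that reproduces the 63/8/11
split of the packaged 82-drug panel. Percentages in the band report are
rounded to whole numbers.

## Dataset preparation

- **Filtering.** Constant/near-constant descriptors (variance ≤ tolerance,
  default 0) are dropped first; then pairs with |Pearson r| ≥ 0.95
  (default) lose their later member, scanning in column order. Both rules
  are logged per descriptor.
- **Normalization.** Min-max to [0, 1], with minima/maxima learned from
  training compounds only. Test values may fall outside [0, 1]; they are
  flagged but kept, since clipping would silently move a compound inside
  the model's domain.
- **Rational split.** Compounds are ranked by activity (exact ties broken
  by a seeded draw), the extremes go to training so prediction stays
  interpolative, and the remaining ranks are cut into `n_test` contiguous
  bins whose middle members form the test set. This yields a test set
  spanning the activity range, and 72 compounds with `n_test = 14` gives
  the 58/14 partition used throughout. The seed affects only tie-breaks.

## Regression and fitting statistics

OLS with an intercept, solved by QR decomposition of the augmented design
(stable under near-collinearity; rank deficiency raises). Coefficient
standard errors come from the unbiased residual variance and (X'X)⁻¹
reconstructed from the R factor. Reported statistics: R²,
R²_adj = 1 − (1−R²)(n−1)/(n−p−1), standard error of the estimate
s = √(RSS/(n−p−1)), F = (R²/p)/((1−R²)/(n−p−1)) with its p-value from the
F(p, n−p−1) distribution, RMSE_tr = √(RSS/n), MAE_tr, and Lin's
concordance correlation coefficient
CCC = 2·Sxy / (Sxx + Syy + n(x̄−ȳ)²).

## Internal validation

Q²_LOO uses the exact hat-diagonal identity e₍₋ᵢ₎ = eᵢ/(1−hᵢᵢ), verified in
tests against explicit per-point refits; PRESS = Σe₍₋ᵢ₎²,
Q²_LOO = 1 − PRESS/TSS, RMSE_cv = √(PRESS/n). A leverage of 1 makes the
deleted residual undefined and raises.

Leave-many-out removes ⌈fraction·n⌉ compounds per iteration (default
fraction 0.3, 100 iterations) and scores held-out predictions against the
retained-subset mean. Per-iteration Q² is reported, but the headline
`q2_lmo` **pools** squared errors and baseline deviations over all
iterations: with very small hold-out groups the per-iteration denominator
can approach zero, making the mean of per-iteration Q² arbitrarily
unstable (at fraction = 1/n it is routinely below −3 while the pooled
value agrees with Q²_LOO to ~0.02). The pooled form is the stable
estimator and reduces to LOO as the fraction shrinks.

## External validation

With press_ext = Σ(y − ŷ)² over the prediction set:
RMSE_ext = √(press_ext/n_ext); MAE_ext; Q²_F1 = 1 − press_ext/Σ(y_ext −
ȳ_train)²; Q²_F2 = 1 − press_ext/Σ(y_ext − ȳ_ext)²; Q²_F3 = 1 −
(press_ext/n_ext)/(TSS_train/n_train); R²_ext is the squared Pearson
correlation of observed vs predicted (so r_ext = √R²_ext); CCC_ext is
Lin's coefficient on the same pairs.

## Y-scrambling

The response is randomly permuted (seeded Fisher–Yates via the numpy
generator) while descriptors stay fixed; R² and Q²_LOO are recorded per
permutation (default 100). Because the design is unchanged, the refit is a
single projection per permutation, which tests confirm equals a fresh OLS
fit. A sound model needs mean scrambled R² > mean scrambled Q², and both
far below the real model's values; for pure-noise responses mean scrambled
R² ≈ p/(n−1), which the suite checks at 500 permutations.

## Acceptability rules

R² ≥ 0.6, R²_ext ≥ 0.6, CCC ≥ 0.85, RMSE_tr < RMSE_cv, and the
Y-scrambling ordering above. Each flag is computed literally from these
thresholds; no combined score is invented.

## K index, QUIK rule, GA

The K multivariate correlation index of a column block uses the
eigenvalue-dispersion form: with λ the eigenvalues of the block's
correlation matrix and λ' = λ/Σλ, K = Σ|λ'ⱼ − 1/p| / (2(p−1)/p), giving 0
for mutually orthogonal and 1 for perfectly collinear columns; p = 1
returns 0 by convention. The QUIK rule computes Kxx (descriptors) and Kxy
(descriptors + response) and passes a subset iff ΔK = Kxy − Kxx ≥ 0.05
(default, configurable). For a single descriptor ΔK reduces exactly to
|r(x, y)|. Note a consequence of the eigenvalue form: a response
duplicating a block member *raises* Kxy, so such models pass QUIK — the
rule screens out blocks more correlated among themselves than with the
response, not duplicated information per se; the separate
cross-correlation screen (reject any descriptor pair with |r| > 0.7)
handles redundancy.

The GA evolves fixed-size descriptor subsets: tournament selection (k=2),
crossover keeping members shared by both parents and filling from their
symmetric difference, single-member swap mutation with probability 0.20,
and elitism (2). Defaults are a population of 200 evolved for 2000
generations ("iterations" is read as generations); inadmissible subsets
(QUIK fail, cross-correlation fail, rank deficiency) receive fitness −∞.
Fitness defaults to Q²_LOO (R² optional). Every evaluated subset is cached
by its member set, and the final ranking deduplicates over all evaluated
subsets; ties break lexicographically on descriptor names so runs are
fully reproducible under the seed. On instances small enough to enumerate,
the GA provably returns the exhaustive-search optimum (tested).

The model ladder runs the GA once per size 1..8 (seed offset by size) and
additionally considers the greedy one-descriptor extension of the previous
winner, so training R² never decreases with size even though selection is
by Q²_LOO.

## Applicability domain

Leverages are hat values against the intercept-augmented training design;
their sum over training rows is p+1 exactly. The warning leverage is the
conventional h* = 3(p+1)/n. Standardized residuals divide LOO residuals by
RMSE_cv for training compounds and external residuals by RMSE_ext for test
compounds ("± 3δ" is read as |z| > 3 in these units); the standardization
denominator is a recorded choice — per-point deleted variances would be an
alternative. Flags are invariant to affine rescaling of the response.

## Fixed published equations

The eight fitted TEAC equations are shipped verbatim with their ±
uncertainties (interpreted as one standard error) and descriptor
metadata. Inputs must be normalized to the original training min/max,
which is not public, so scoring raw descriptor values is deliberately
unsupported. Negative predictions are returned with a warning rather than
clamped — the equation is linear and clamping would hide extrapolation.
The eight-variable equation's last descriptor is spelled F06[N-F] in the
equation listing but F06[N-S] in the metadata table of the source; both
spellings are shipped, cross-referenced by a note.

## Synthetic data generator

Descriptors are latent standard normals. Informative columns are
independent; noise columns form consecutive blocks of 5 sharing a latent
factor, x = √ρ·f + √(1−ρ)·ε, giving exact expected within-block
correlation ρ (default 0.8); constant columns (default 3) exercise the
pre-filter. The activity is
`intercept + Σ coef·minmax(x) + N(0, noise_sd)`, optionally clipped at 0
(clipped points kept, not resampled, as a non-negative assay readout
would produce). The study-scale recipe uses 72 compounds, the published
four-variable coefficients (Mor16e −0.0851, RDF145p −0.1511, C-018 0.1489,
CATS2D_06_AL 0.1991, intercept 0.0396), residual SD 0.0428 mM — the
reported standard error of the four-variable fit — and 200 noise
descriptors. Generated activities then fall in [0, ~0.34] with means near
0.1, matching the measured panel's 0–0.302 mM scale, and refitting the
true columns gives s between 0.03 and 0.06.

What the generator does *not* emulate: real descriptor marginals (the
distribution of commercial descriptor values is unknown; normal latents
are a stand-in), cross-family correlation structure, and any relation
between descriptor values and chemical structure. Passing tests therefore
demonstrate the statistical machinery, not chemical validity.

A consequence worth stating plainly: at the study's signal-to-noise level
(weakest informative coefficient ≈ 1.6–3.5 residual SEs) an exhaustive or
GA search over ~200 candidate descriptors at n = 58 frequently finds a
subset with *higher* Q²_LOO than the planted truth — ordinary selection
bias. In repeated simulations the planted subset ranks first in roughly
55–65% of runs. Exact subset identification at this signal level is not a
reliable property of any selector, which is precisely why the
cross-correlation screen, QUIK rule and external validation exist.

## Problem sizes used in the test suite

Simulation-backed tests use n = 58 training compounds (the study's
training size), 100 replicates for coefficient-coverage checks, 20 seeded
runs for GA recovery, 100–500 permutations for Y-scrambling, and 50 seeds
for Williams-plot outlier rates; these sizes give Monte-Carlo error well
inside the asserted margins.

## Known limitations

- Descriptor computation from structures is out of scope; real use
  requires externally computed, pre-normalized descriptors.
- The published equations cannot be applied to raw descriptor values
  (normalization constants unpublished).
- The LMO baseline uses the retained-subset mean; a global-mean variant
  would differ slightly and is configurable at the call site.
- The GA is single-population; no islands or multi-objective selection.
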