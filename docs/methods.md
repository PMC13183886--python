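# Methods

## Scope and model

The package implements a wrapper feature-selection method for binary
clinical risk prediction: candidate predictor subsets are scored by the
cross-validated accuracy of a random forest restricted to them, penalized
for subset size, and the score is maximized by an improved squirrel-search
metaheuristic (ISSO/ESSO — two names for the same algorithm, both used in
the literature it comes from). Post-hoc attribution (Shapley values and a
local linear surrogate) explains the resulting classifier at the level of
original clinical features.

## The objective

For a mask `S` over `m` predictors,

    fitness(S) = α · Accuracy_CV(S) − β · |S|/m,   defaults α = 0.9, β = 0.1.

`Accuracy_CV` is the mean stratified k-fold CV accuracy (default k = 10) of
a forest of `n_trees` Gini trees (default 100, unrestricted depth,
min-split 2, bootstrap on) trained on the masked columns. An empty mask is
invalid; repair always keeps at least one bit. At the default *group*
granularity a mask bit toggles all one-hot columns of one original
feature, so `m` counts clinical features (13 for the heart-disease
schema), not encoded columns.

## Optimizer mechanics and constants

Squirrels are continuous positions in `[0,1]^m`, thresholded at 0.5
(configurable) into masks. This reconciles "binary vectors" with gliding
motion toward better squirrels: movement is continuous, the evaluated
object is binary. Per iteration: rank by fitness (ties prefer smaller
subsets, then lower index); rank 1 is hickory, ranks 2..⌈N/2⌉ oak, the
rest normal. Oaks glide toward the hickory; normals glide toward a random
oak with probability 0.5, else the hickory. The glide update is

    x ← clip(x + dg(t) · Gc · (target − x), 0, 1),
    dg(t) = dg_max − (dg_max − dg_min) · t/(T−1),

with `Gc = 1.9`, `dg_max = 1.11`, `dg_min = 0.5` — the source method names
an "adaptive gliding distance" without a formula, so the linear decay and
the constants are taken from the original squirrel-search literature and
are all configurable. Each non-hickory squirrel then faces a predator with
probability 0.1 (uniform relocation); bits flip independently with
probability 0.01 (positions are redrawn within the matching half-interval
so mask and position stay consistent); every 10 iterations a seasonal
check relocates the worst ⌊N/2⌋ squirrels if the best fitness did not
improve over the window (the source states "part of the population"
without a fraction; half is the package's choice, with the hickory always
retained). Defaults N = 30, T = 50. Elitism makes the best-ever trace
non-decreasing; there is no separate convergence criterion beyond the
fixed budget.

`exhaustive_search` enumerates all non-empty masks (refused above m = 15)
under the same memoized evaluator and is the testing oracle;
`random_search` draws uniform masks at a matched evaluation budget and is
the efficiency baseline.

## Preprocessing

Fixed order, fit on training data only: KNN imputation (numeric cells get
the mean of the k = 5 nearest donor rows by Euclidean distance over
mutually observed, min-max-scaled numeric columns; categorical cells get
the column mode), min-max normalization (fit columns land on [0,1]
exactly; stored min/max are reused on new rows without clipping), one-hot
encoding (full expansion, one indicator per level; the group map ties
indicators to their clinical feature; unseen levels become an all-zero
block with a warning), z-score outlier *reporting* at |z| > 3 (strict;
computed on pre-normalization values — z-scores are scale-invariant so the
choice is cosmetic; rows are flagged, never removed, because extreme but
clinically plausible values carry signal), and greedy correlation pruning
at |r| > 0.85 (strict; the dropped member of a pair is the one with larger
mean absolute correlation to the remaining columns — the source does not
specify the tie-break). Pruning incidentally removes one indicator of
every two-level feature (complementary indicators have r = −1), which is
what brings the encoded 13-predictor table from 25 columns into the
published ~20–22 range.

SMOTE balances classes by interpolating a minority row toward one of its
k = 5 minority nearest neighbours with a Uniform(0,1) coefficient, so every
synthetic row is a convex combination of two minority rows. It runs only
on training data: once per training fold inside the fitness evaluator
(in the full encoded space, before column masking — matching a pipeline
that balances before selecting) and once on the full training partition
before the final fit. Indicator coordinates of synthetic rows stay
fractional; the downstream model is tree-based and indifferent.

## Evaluation protocol

`run_pipeline` draws a stratified 80/20 split, fits the chain and the
optimizer on the training side only, fits the final forest on the
(SMOTE-balanced) training set restricted to the selected mask, and reports
test-set accuracy, precision, recall, F1, Mann–Whitney AUC and confusion
counts, alongside the cross-validated training accuracy. Both are reported
because the source protocol mixes them. Precision with no predicted
positives is recorded as 0 with an explicit flag. The report carries a
leakage audit: the held-out indices and the optimizer-visible indices,
asserted disjoint.

## Explanations

Shapley values use the interventional value function: `v(S)` is the mean
model score over background rows (default: 100 training rows sampled with
the pipeline seed) with the instance's values spliced in on `S`.
Conditional expectations would need a density model; the interventional
reading keeps the axioms exact and is the package's choice where the
source does not specify. `shapley_exact` enumerates all `2^m` coalitions
(refused above 15 groups) and satisfies efficiency to numerical precision;
`shapley_sampled` is the permutation estimator with per-feature
Monte-Carlo standard errors. Attributions are computed at group level so
statements about one clinical feature are well-posed after encoding.
`global_importance` ranks features by mean |φ| over instances.

The local surrogate perturbs numeric coordinates with Gaussian noise
scaled by the training standard deviation and resamples categorical
groups from training marginals, weights perturbations by
`exp(−d²/kernel_width²)` (distance in standardized space, default width
`0.75·√m` — a common surrogate default, none is given by the source), and
fits a ridge-penalized weighted least squares (α = 1e−3, negligible bias
at thousands of samples) of model scores on the standardized design.
Coefficients therefore live on the standardized scale: for a linear score
`β·x` the expected coefficient is `β_j · sd_j`.

## Synthetic data

The generator emulates the clinical schema: correlated Gaussian numeric
columns (requested pairwise r via Cholesky), multinomial categorical
columns with Dirichlet-drawn marginals, and a Bernoulli target from a
logistic model over standardized informative columns, with the intercept
solved numerically for the requested prevalence. Missingness is injected
completely at random (the source never characterizes its missingness);
the target is never masked. The frozen default fixture (`PLANTED_SPEC`)
uses n = 600, m = 20, five informative features with absolute log-odds
effects ≥ 0.8, three categorical noise columns and balanced classes —
strong, well-separated effects a clinical cohort of this size could
realistically show, chosen so the informative subset is identifiably
fitness-optimal. What the generator does **not** reproduce: real clinical
marginals and nonlinear interactions, informative missingness, label
noise from diagnostic disagreement. Passing tests therefore demonstrate
correctness of the machinery and recoverability under known ground truth,
not expected accuracy on any real cohort.

The spec-level `prevalence` fully determines the class-imbalance ratio for
a binary target, so no separate imbalance knob exists.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the searches at reduced
scale, as their own configuration choice: fitness uses 3-fold CV with
10–25 trees; the oracle-dominance study uses 10 instances with m = 8,
n = 200 and the published optimizer budget (N = 30, T = 50 — cheap there
because the exhaustive oracle has already memoized the whole 255-mask
space); the recovery study runs the frozen planted fixture with
N = 10, T = 12 per seed. Thresholds under test (recovery ≥ 4/5 planted in
≥ 80% of seeds, oracle equality in ≥ 70%, Shapley efficiency 1e−9,
sampled-Shapley error < 0.01 at 2000 permutations, surrogate coefficients
within 10%) are never adjusted to the budget.

## Known limitations

Fitness is noisy at small n and few folds, so distinct masks can tie and
the "optimal" subset is only defined up to that noise. The wrapper cost
scales as O(N·T) forest fits (memoization removes repeats). Exact Shapley
is exponential in the number of groups. The correlation-pruning greedy is
order-dependent by construction; the recorded removal list makes it
reproducible. No multi-objective variant, no chaotic-map or Lévy-flight
squirrel variants, no calibration analysis.
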