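# Methods

This note documents the models and procedures implemented in `ensdm`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Occurrence preparation

Thinning is greedy: records are visited in a seeded random order and a record
is kept iff it lies more than `radius_km` (default 1.0) from every
already-kept record. The result always satisfies the pairwise-separation
property exactly; *which* maximal separated subset is kept depends
deterministically on the seed, which is logged. Distances are great-circle
(haversine, R = 6371 km) for geographic coordinates and Euclidean for
abstract grids — the pipeline switches automatically on the stack's CRS tag.

Pseudo-absences are uniform draws without replacement from valid,
non-presence cells, placed at cell centres; each of the `n_sets` sets uses a
derived seed (`seed + set index`). Presences carry weight 1 and each
pseudo-absence `(n_presence/n_pa)·prevalence/(1−prevalence)`, so prevalence
0.5 equalizes total class weights for any sample sizes. Train/test splits
are stratified per class with train size `round(0.75·n)` (half-up, capped to
leave at least one test point); fewer than 4 presences is an error.

## Screening

Contribution rates use prediction-permutation importance on a preliminary
full-variable GBM: for variable j, `1 − Pearson(ref, pred with column j
permuted)`, averaged over 5 shuffles, clipped at 0, normalized to 100 %.
Correlations are computed over all valid cells of the current stack (not just
sample points) — the convention of landscape-level correlation screens; both
choices are configurable because neither is uniquely standard. Screening
visits variables in descending contribution (ties alphabetical): drop if
contribution < 0.5 % (strictly below, so a variable at exactly the boundary
survives — the rule that reconciles a "≤ 0.5 excluded" criterion with a
retained boundary case) or if `|r| ≥ 0.8` against an already-retained
variable. The retained set therefore never contains a pair at or above the
correlation ceiling.

## The maxent-style learner

Variables are min–max scaled to [0, 1] using the statistics of the *combined*
presence+background model matrix (the maxnet convention; background-only
scaling would clamp presences outside the background range). Projection
values are clamped to the training range ("clamping"). Feature classes:

* L: `x`; Q: `x²`; P: `x_a·x_b` for all pairs;
* H: forward hinges `max(0, (x−k)/(1−k))` and reverse hinges
  `max(0, (k−x)/k)` at `n_hinge_knots` (default 50) evenly spaced interior
  knots;
* T: step indicators `1[x > k]` at `n_threshold_knots` (default 50) knots.

The model is an L1-penalized logistic presence-vs-background regression on
these features. The penalty on feature j is `RM · b_class · √m` with m the
presence count and base penalties 0.05 (L/Q/P), 0.5 (H), 1.0 (T): hinge and
threshold classes are discouraged roughly one and two orders of magnitude
more strongly than linear terms, and the √m scaling makes the *relative*
shrinkage decay like 1/√m, the behaviour of maxent's sample-size-dependent
defaults. Per-feature penalties are realised by column rescaling before a
uniform-penalty fit (the `penalty.factor` device), so RM → ∞ provably zeroes
all coefficients and RM → 0 approaches the unpenalized fit. Output is the
plain logistic response in [0, 1]; no cloglog transform is applied anywhere,
and all downstream thresholds operate on this scale.

### AICc and tuning

`AICc = 2k − 2 ln L + 2k(k+1)/(n−k−1)` with k the number of nonzero
coefficients and n the presence count; combinations with `n − k − 1 ≤ 0` are
invalid. The likelihood normalizes the **predicted suitability** over the
presence+background sample (so probabilities sum to 1) and sums the log
probability over presences. Normalizing `exp(raw score)` instead was
considered and rejected: under a Bernoulli fit the true log density-ratio
saturates wherever suitability approaches 1, a shape an
exponential-of-linear-score cannot represent, and that variant systematically
selects hinge features even when the generating response is linear on the
logit scale. With suitability normalization, tuning on linear-truth data
selects FC = L or LQ in 10/10 seeded replicates.

Tuning evaluates every RM × FC pair (default 8 × 6 = 48): one fit on a seeded
stratified 75/25 split for held-out AUC, one on the full sample for AICc.
Selection: ΔAICc = 0, ties broken by higher AUC, then smaller RM, then
shorter FC string; the ΔAICc < 2 set is reported as "reliable".

## Standard learners

All standard algorithms sit behind the same contract and use fixed,
documented settings: GLM is an unpenalized logistic regression on a
**quadratic** formula (each standardized predictor linear and squared — the
default formula of the reference ensemble platform, and necessary for any
non-monotone response); GAM is a cubic-spline-basis logistic with ridge
penalty; CTA a classification tree (min leaf 5); RF a 200-tree random
forest; GBM 100 rounds of depth-3 gradient boosting; ANN a standardized-input
multilayer perceptron (8 hidden units); XGBOOST 100 rounds of depth-3
boosting; MARS an adaptive piecewise-linear model — per-variable
forward/reverse hinge bases with L1 selection (no interaction terms); FDA a
linear discriminant on the same hinge basis. Sample weights are honoured
where the backend supports them (all but ANN and FDA, which is noted in
their docstrings). A learner that fails to fit produces a `"failed"` member
record and the protocol continues — member failure is data, not a crash.

## Evaluation and ensembling

AUC is the rank-based (Mann–Whitney) statistic, ties counting ½. TSS sweeps
candidate thresholds at the midpoints of consecutive sorted unique scores
plus 0 and 1 (exact maximization; smallest argmax on ties); a point is
predicted present iff its score exceeds the threshold. Test folds are scored
unweighted — weights shape fitting only.

The member table crosses algorithms × pseudo-absence sets × repetitions.
Gating is at algorithm level (mean AUC > 0.90 and mean TSS > 0.80, strict),
because whole algorithms, not runs, are the natural unit of a committee; a
run-level gate is available. Ensemble weights are proportional to member
TSS (a run-level quantity), renormalized to 1; AUC- or mixed-weighting was
left out to keep one deterministic convention. A member that fails at
prediction time is dropped with renormalization and a warning.

Response curves use the evaluation-strip method: sweep one variable over its
observed valid-cell range (100 points) holding all others at their valid-cell
medians.

## Habitat accounting

Grades: 1 (P ≤ 0.3), 2 (0.3 < P ≤ 0.6), 3 (0.6 < P ≤ 0.85), 4 (P > 0.85).
Binarization is presence iff P > 0.3 — exactly 0.3 is absence, forced by
consistency with grade 1 covering P = 0.3. Change analysis defaults to the
moderate+high class (grade ≥ 3) because that is the class the
transition-rate accounting is defined on; the P > 0.3 variant is a config
switch. Expansion and contraction rates divide by the previous-period
suitable area (retained + loss) — the identity that reproduces every rate in
the reference accounting exactly. Areas are summed at full precision and
rounded to 2 decimals (in 10⁴ km²) only in reports. The cell-area model is
either constant (default 1 km², making counts and areas interchangeable on
abstract grids) or latitude-cosine, `(R·Δ)²·cos(φ_row)` with Δ in radians —
the method for converting a geographic grid to km² is not uniquely defined
at arc-second resolutions, so both conventions are exposed.

## MESS / MoD

The piecewise rank formula (with f the percentage of reference values
strictly below the query): f = 0 → `100·(p−min)/(max−min)`; 0 < f ≤ 50 →
`2f`; 50 ≤ f < 100 → `2(100−f)`; f = 100 → `100·(max−p)/(max−min)`. The cell
score is the minimum over the screened variables, the MoD its argmin
(smallest index on ties). The reference sample defaults to the model
training points (presences + the selected pseudo-absence set); presences-only
is a config switch. Note that a reference point lying exactly at the sample
minimum of some variable scores S = 0 for that variable, so self-similarity
is S ≥ 0, not strictly positive. Reporting bins follow the anomaly legend:
extreme (S < 0), anomalous (0 ≤ S < 10), similar otherwise.

## Synthetic landscape

Each layer is Gaussian-filtered white noise (kernel width 6 cells on the
default 120 × 120 grid, ≈ 400 effective independent patches), standardized to
mean 0 / sd 1. Near-duplicate pairs are engineered as
`r·source + √(1−r²)·independent` (defaults: copies of two truth-active
layers at target r = 0.97 and 0.95) to give the correlation screen real work.

The truth surface is `P = logistic(β0 + Σβ_j z_j + Σγ_j z_j²)` on z-scored
layers; the default uses 3 of the 12 layers — a unimodal
temperature-optimum-style response (β = 12, γ = −6) plus two linear terms
(−7, −5). β0 is calibrated per realization by root finding so the
landscape-mean suitability equals 6.5 % — the virtual-species device for
pinning niche prevalence, set to the suitable-domain share typical of a
sharply climate-limited species occupying a small fraction of a large
domain. Steep coefficients make the niche boundary crisp; with gentle
coefficients the occupancy process itself is so noisy that no learner — nor
the generating model — can reach the gate thresholds, which would say
nothing about the pipeline.

Presences are drawn without replacement with probability ∝ P, at cell
centres plus ±0.3-cell uniform jitter (so thinning at a 1-cell radius has
real effect). Future scenarios are deterministic per-layer affine shifts;
the default bundle includes a mild shift toward the optimum (suitable area
grows) and a beyond-range shift (every cell becomes MESS extrapolation with
the shifted layer as MoD). When rescoring truth on a shifted stack, the
reference period's standardization and calibrated intercept are reused —
otherwise the calibration would re-pin prevalence and hide the shift.

**What the benchmark shows and does not show.** Passing tests establish that
the pipeline recovers a known smooth, low-dimensional logistic niche from
presence-only data at realistic sample sizes (Spearman ρ ≥ 0.8 between
ensemble suitability and truth in ≥ 8/10 seeds), that screening removes
engineered redundancy, and that the accounting and anomaly layers are exact.
The synthetic landscape has no sampling bias, no observation error in
coordinates beyond jitter, isotropic smooth fields rather than real
bioclimatic covariance, and truth within the span of the feature classes —
real-data performance, and the real-data choice of RM/FC or retained
variables, are outside what these tests can certify.

## Numerical and determinism choices

One master seed drives everything; stages derive seeds by fixed offsets
(thin +10, pseudo-absences +20, splits +30, importance +40, tuning +50,
protocol +60; members additionally by `7919·rep + 104729·pa_set`). Reruns
with the same config and seed reproduce all tables byte-identically. ESRI
ASCII grids are written with 6 significant digits and nodata −9999; both
corner- and centre-registered headers are read, normalized to corner. Grid
alignment uses absolute tolerance 1e-9 on all six geometry fields. Cells are
addressed by `floor((x−x0)/cell)` with half-open intervals, row 0 at the top.
Degenerate (constant) variables are skipped with warnings in feature
expansion, correlation and MESS rather than erroring the run.

## Known limitations

No reprojection or resampling — inputs must be pre-aligned; GeoTIFF is not
read (ESRI ASCII only). MAXENT and MAXNET share one core implementation
(default vs tuned feature specification). MARS carries no interaction terms.
The FDA and ANN backends ignore case weights. MESS is the rank-based
similarity only; model-sensitivity-based limiting-factor variants are out of
scope.
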