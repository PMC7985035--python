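# Methods

## Model and objective

The per-modality model is a two-layer feed-forward network whose output
is a per-sample log hazard ratio (prognostic index, PI) under a
proportional-hazards assumption: η(x) = βᵀ a(Wᵀx + b) with a = tanh and
no output bias, since the partial likelihood is invariant to shifting η
and an output intercept would be unidentifiable. The hidden width is
⌊√p⌋ (minimum 1), so a 2429-feature image table gets 49 hidden nodes and
a 100-feature table gets 10.

The training objective is the Breslow partial log-likelihood — tied
event times share the full risk-set denominator — **averaged over
events** and penalized by λ(‖W‖² + ‖β‖²). Averaging (rather than
summing) keeps the gradient magnitude, and hence the behavior of the
fixed learning rate, stable across sample sizes; reported log-likelihood
values elsewhere in the package (importance scores, the
`cox_partial_log_likelihood` function) are unnormalized sums. All
gradients are derived analytically and verified against central finite
differences (relative error below 1e−5) in the test suite.

Optimization is plain full-batch gradient ascent with a fixed step of
0.01 for 500 epochs; momentum exists behind a config flag but is off by
default so that a seed fully determines the weight trajectory. Weights
are initialized Glorot-style (scaled uniform) from the run seed.
Inverted dropout (rate 0.7, masks resampled per epoch per sample and
hidden unit, activations scaled by 1/(1−rate) at train time) regularizes
the hidden layer; inference is deterministic with dropout off. Inputs
are z-scored per column with training-split statistics stored on the
model, because mixed-unit feature tables make fixed-step training
unstable otherwise. A divergent configuration (non-finite objective) is
reported with an explicit error rather than silently producing NaN; the
stability bound for the ridge term under step size γ is λ < 1/γ.

## Model selection and evaluation

The L2 penalty is chosen by grid search (default grid 1e−4…1, five
log-spaced points) under 5-fold cross-validation, scored by the mean
validation partial log-likelihood per event — the training objective,
not the C-index, which is reported alongside. Folds are shuffled with
the run seed; a fold with zero events is reshuffled once and then
rejected. A grid point that diverges under the fixed step is scored −∞
instead of aborting the search.

Evaluation is repeated random 80/20 hold-out (20 repetitions by
default), each repetition re-running the grid search on its own
training split. The concordance index implements the strict
pair-counting rule: a pair is usable when the shorter observed time
belongs to a sample whose event was observed and the times differ; ties
in the predicted score count as discordant. Other packages award ½ per
score tie, so comparisons can differ in the third decimal on tied
predictions. Risk dichotomization uses the median PI with the rule
η ≤ median → low risk; when ties at the median would empty a group, a
rank split at ⌊n/2⌋ restores two groups. On held-out data the threshold
is the **training-split** median, since a threshold computed on test
data leaks outcome information; this choice affects log-rank p-values
and is therefore fixed package-wide. Kaplan–Meier curves and the
two-group log-rank test (chi-square with 1 df, asymptotic p) are
delegated to lifelines behind the package's own function surface; tests
validate them against hand-computed product-limit and O/E/V tables.

## Two-stage fusion

Stage-1 networks are trained per modality; their hidden activations are
concatenated (column provenance tracked as modality × node) and a
stage-2 network with its own ⌊√·⌋-width hidden layer and its own grid
search is trained on the fused matrix. Everything — both stage-1 fits,
their hyperparameter searches, and stage 2 — runs inside each hold-out
training split; `fuse_and_train` hard-errors if a stage-1 model was not
fitted on exactly the stage-2 training samples. Stage-2 inputs are
z-scored like any feature matrix (tanh activations are bounded but not
centered). Saved two-stage archives embed the stage-1 extraction
weights, so a loaded archive predicts standalone.

## Feature importance and association

Mean-substitution importance replaces one column by its mean (by
default the mean of the supplied data; pass training-split means when
scoring elsewhere) and takes the drop in the unnormalized partial
log-likelihood under the deterministic forward pass. Ties are broken
lexicographically by feature name so rankings are reproducible.

Association analysis regresses each top image feature on each top gene
feature (simple least squares; r, r² = r², two-sided slope p). Edges
require |r| above the image–gene threshold (default 0.1) **and**
p < 0.05 — absolute correlation, because protective and harmful features
both occur. Gene–gene edges use Pearson correlation > 0.5 on the same
matrix used for modeling. No multiple-testing correction enters the
filter; a Benjamini–Hochberg q-value column is emitted alongside, marked
as an extension, for the user's judgment. Node hazard signs come from
univariate lifelines Cox-PH fits on standardized features; |z| < 1 or
non-convergence flags the sign as unstable/indeterminate.

## Image front-end

Tumor-region images are cut into non-overlapping `tile_size`-square
tiles (default 1000 px); partial tiles at the right/bottom margins are
discarded because fractional tiles would bias the density comparison.
Tile "density" is the literal sum of R+G+B over the tile. On H&E slides
that literal sum favors bright, background-heavy tiles, since tissue is
darker than background; whether bright or tissue-dense tiles were
intended is genuinely ambiguous, so both are provided —
`density_mode="sum"` (literal, default) and `"inverted-sum"`
(Σ(255−channel), favoring dark tissue). The top k = 10 tiles are kept,
ties broken by (row, col); selection happens before normalization.
Channel normalization multiplies each channel by (reference channel
mean / image channel mean) against a user-supplied reference image;
outputs stay in float and are clipped to [0, 255], with a warning when
clipping moves the achieved means off the reference. Per-tile feature
tables (e.g. CellProfiler exports) are collapsed to one row per patient
by the per-feature median across tiles, NaNs excluded per feature.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes of
a real cohort: standard-normal feature blocks (optionally equicorrelated
informative features via a shared latent factor), a sparse linear risk
score (optional quadratic term on the first driver), exponential event
times with rate ∝ exp(η) (Weibull behind a flag), and independent
exponential censoring whose scale is calibrated by bisection to hit a
target censored fraction within ±0.005 (hard error beyond ±0.05). The
default cohort is 500 samples × 100 features with 5 informative features
at effect size 2 per SD — chosen so the true risk score alone exceeds
0.9 concordance on uncensored data, i.e. an unambiguous "strong signal"
— under 30% censoring, echoing the scale of a TCGA-sized cohort at desk
cost. The complementary-modality generator gives two feature blocks with
disjoint drivers summing to the true risk, so fusion is strictly more
informative than either modality by construction.

What the generator does **not** emulate: real CellProfiler feature
distributions (heavy tails, bounded supports, redundancy among the 2429
summaries), RNA-seq count noise and normalization artifacts, batch
effects, or informative censoring. Passing tests therefore demonstrate
correctness of the procedures and the qualitative fusion advantage under
proportional hazards — not clinical-grade performance on pathology data.

## Problem sizes and numerical choices

Test experiments run at n = 120–500 samples and p = 9–100 features with
10-seed medians for the multi-seed claims, sizes at which every
conclusion the tests assert (signal recovered, fusion superior, noise at
chance) is already stable. The acceptance script's anchors use n = 100
(perfect predictor) and n = 200 with 200 score draws (random predictor).
Deterministic contracts are exact: same seed → bit-identical weights,
predictions, and archive bytes (model archives are written with fixed
zip timestamps for this reason). Numeric tolerances elsewhere: partial
likelihood vs brute force 1e−10; gradient check 1e−5 relative; channel
means after normalization 0.5 intensity units (clipping slack).

## Known limitations

Single hidden layer only; no mini-batching, GPU paths, or early
stopping. No competing risks, time-varying covariates, stratified
models, or interval censoring. Complete cases only across modalities
(samples are inner-joined by id). The Efron tie correction is not
implemented (Breslow only, chosen as the simplest consistent
convention; the partial-likelihood code isolates the denominator so an
Efron variant can be swapped in). C-index tie handling is the strict
rule by design, documented above.
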