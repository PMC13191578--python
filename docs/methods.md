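# Methods

## Problem setting

Flue-cured tobacco leaf is assigned one of three aroma types — fresh-sweet
(0), honey-sweet (1), mellow-sweet (2) — by sensory evaluation. The package
models aroma type as a function of 51 continuous chemical indices (mg g⁻¹)
and provides the full chain from feature engineering to an interpreted,
tuned classifier. All statistical machinery assumes a three-class label in
{0, 1, 2} and strictly positive contents; neither is revisited downstream.

## Feature derivation

For *p* primitive indices the derived space holds all pairwise sums over
unordered pairs *including self-pairs* (i ≤ j, count *p*(*p*+1)/2),
differences and ratios over unordered pairs with one fixed orientation
(earlier column first, i < j, count *p*(*p*−1)/2 each). The self-pair
convention for addition and the single orientation for the anti-symmetric
operations are what make the counts land at 1326/1275/1275 for *p* = 51; a
sign flip or reciprocal changes neither tree-model splits nor |Pearson r|,
so one orientation loses nothing. Self-sums (2x) are collinear with their
primitive and are left for the correlation-pruning tier to remove if they
are ever selected. Ratio denominators below 1e-9 in magnitude are floored at
±1e-9 with a warning; with positive chemical contents this never fires on
clean data.

## Separation index

Tier 1 scores each feature and class pair with f = 1.18·|ΔX|/(W₁+W₂), the
chromatographic-resolution statistic with distribution peaks in place of
elution peaks; f > 0.8 (strict) retains, and a feature is kept when *any* of
the three pairs passes. Two peak estimators are provided:

* `gaussian` (default): center = sample mean, width = FWHM of the fitted
  normal, 2√(2 ln 2)·s ≈ 2.3548·s with the ddof-1 sample SD. Deterministic
  and closed-form testable; under equal variances the threshold f = 0.8
  corresponds to a mean separation of ≈ 3.19 σ.
* `kde`: center = mode of a Silverman-bandwidth Gaussian KDE on a 512-point
  grid, width = distance between the two half-height crossings around the
  mode (linear interpolation), the literal frequency-distribution-peak
  reading. The grid is widened once (×4 padding) if a crossing falls
  outside; multimodal shapes use the global mode only, consistent with the
  unimodal-peak assumption.

Features with zero spread in a class score 0 for the affected pair (with a
warning) rather than aborting a 3927-column scan. Both estimators are
affine-equivariant, so f is invariant under rescaling/unit changes.

## Screening cascade

Tier 2 fits a 100-tree random forest (min_samples_split 2, min_samples_leaf
1, fixed seed) on each of 5 stratified CV training folds and averages the
mean-decrease-in-impurity importances over fold models — fold-averaging was
chosen over a single full-data refit to reduce variance, with CV already
mandated for the importance model. The top 10 per operation-type dataset
proceed (the primitive dataset keeps all tier-1 survivors, which are few).

Tier 3 computes all candidate pairwise Pearson correlations within each
dataset and greedily resolves pairs with |r| > 0.8 in descending |r|: drop
the lower-importance member; on an exact importance tie, drop the member
whose constituent primitives have the lower mean content (composite content
= mean of its primitives' training means); on a full tie, keep the earlier
column. The per-dataset survivors are unioned and one cross-dataset pass at
the same threshold enforces joint non-redundancy; the pass is flagged in the
report. Importances compared across datasets in that pass come from
different forests and are not on a common scale — in practice the small
primitive dataset concentrates importance mass, so primitives usually win
cross-dataset ties, but a borderline composite can occasionally displace a
primitive marker (observed in roughly 1 in 20 synthetic replicates).

## Synthetic survey generator

The generator emulates the study design the pipeline targets: 619 samples in
classes of 411/151/57, a 51-index catalog spanning conventional components,
sugars, alkaloids, polyphenols, sugar alcohols, organic acids and amino
acids, per-class multivariate Gaussians with block correlation r = 0.3
within substance groups (enough to create redundant derived features for
tier 3 to prune), and strict positivity by resampling non-positive
coordinates from the truncated-positive marginal — clipping would create
point masses at zero that break peak-width estimation and ratio features.

Baseline means and SDs are invented but plausible mg g⁻¹ values (SD ≈ 18% of
mean, hand-set spreads for the four markers); they are fixtures, not claims
about real tobacco chemistry. Default planted effects shift rutin +4 SD in
class 0, chlorogenic acid −4 SD in class 2, anatabine +4 SD in class 2 and
serine +4 SD in class 1, plus mild (≤1 SD) sub-threshold structure. The 4 SD
magnitude puts the markers' Gaussian-limit separation index at
1.18·4/4.7096 ≈ 1.00, above the 0.8 retention threshold with margin (a 3 SD
shift would sit at ≈ 0.75 and be screened out); all configured class means
stay ≥ 3 SD above zero so truncation bias is negligible. What passing tests
on this generator shows: the cascade recovers strong, approximately Gaussian
markers under class imbalance and within-group correlation. What it does not
show: behaviour under skewed or multimodal real distributions, assay noise,
batch effects, or markers near the screening threshold — real surveys are
harder, and the near-perfect model scores on synthetic data should not be
read as expected field performance.

## Modeling and metrics

Preprocessing winsorizes at the training 1%/99% quantiles (the conventional
reading of "capping"; bounds are configurable) and Z-scores with
training-set moments; parameters are fitted on training data only and
reapplied, never refitted, to validation and test parts. The zoo fixes the
six models' parameters: LR (C = 1, balanced), DT (ccp_alpha 0, balanced),
RF (100 trees), XGBoost (100 estimators, softprob; balanced class weighting
realized as per-sample weights), KNN (k = 5), and PLS-DA as a PLS regression
on one-hot labels with 3 components and argmax decision — the standard
construction where no decision rule is otherwise fixed.

Metrics come from the 3×3 confusion matrix: per-class precision (column-wise),
recall (row-wise), F1 (harmonic mean; 0 when both terms are 0), macro values
as unweighted class means, and overall accuracy = trace/total. Macro-F1 is
the core comparison metric because of the class imbalance. No per-class
accuracy is reported: for a single-label problem it collapses to recall.
Cross-validation uses the package's own seeded per-class-shuffle stratified
k-fold (fold proportions within one sample of global); fold metrics are
averaged arithmetically and fold confusion matrices summed.

The train/test split apportions per-class test seats by largest fractional
remainder around round(N·fraction) with ties to the smaller class index —
with sizes (411, 151, 57) at 0.2 this yields (82, 30, 12), the apportionment
consistent with per-class evaluation at those denominators.

## Genetic algorithm

One real-valued chromosome holds all genes; integers are rounded and
booleans thresholded at 0.5 at decode time, keeping a single representation.
Operators: tournament selection (size 3), uniform crossover (probability
0.9), per-gene mutation (probability 0.1; Gaussian perturbation with σ = 10%
of range for reals, uniform resample for integers, flip for booleans),
elitism of 1 — standard defaults, all exposed in `GAConfig`. The stated
population 100 / 50 iterations / precision 1e-6 are the `GAConfig` defaults;
the precision is interpreted as a stall rule (stop after 5 consecutive
generations improving the best fitness by less than 1e-6). Fitness for
forest tuning is the training-split 5-fold CV macro-F1 — the core metric,
computed without touching the held-out test set — and evaluations are cached
on the decoded genotype. Elitism makes the best-fitness history
non-decreasing; all chromosomes are clipped to bounds after every operator.

## Shapley estimator

Attributions are Monte-Carlo permutation Shapley values in per-class
probability units: for each permutation, features switch one at a time from
a background row's values to the explained sample's, and each class-probability
delta is credited to the switched feature. Background rows are cycled in a
balanced, seeded order rather than sampled independently — the per-path
deltas telescope, so the efficiency identity (base value + Σφ = predicted
probability) is exact whenever the permutation count is a multiple of the
background size, and the remaining Monte-Carlo error concentrates where it
matters, on the per-feature split. The estimator is validated against exact
enumeration of all d! orderings on ≤ 5-feature models. Default background:
up to 100 training rows, seeded. Dependence thresholds are read off the
first sign change of a centered moving average (window max(5, n/20)) of the
attributions sorted by raw feature value, with linear interpolation between
the bracketing samples; reported content thresholds are therefore estimates
of where a feature's contribution to a class flips sign, validated on
generator-planted crossings. PCA runs on Z-scored features and exports
scores, loadings and explained-variance fractions.

## Pipeline driver and problem sizes

`run_pipeline` chains the stages with all randomness derived from one seed
and serializes a sorted-key `report.json`, so same-seed runs are
bit-identical (wall-clock time is kept out of the reproducible report). The
driver's defaults scale the expensive stages — GA population 12 over 10
generations and 50 Shapley permutations — which completes a full 619-sample
run in a few minutes on one CPU; `GAConfig` retains population 100 / 50
generations for standalone tuning, and the Shapley default elsewhere is 200
permutations. Test-suite and acceptance-script problem sizes (e.g. 20
screening replicates, a 210-sample tuning table, 60-member GA populations on
analytic objectives) were chosen as the smallest sizes at which the checked
properties are stable.

## Known limitations

* The separation index assumes unimodal, roughly symmetric class
  distributions; the KDE variant tolerates skew but still uses one peak.
* Cross-dataset pruning compares importances from different forests (scales
  not commensurable); the tie direction is deterministic but heuristic.
* The GA does not include "no depth limit" in its max_depth range (3–20), so
  the default forest is not exactly representable; tuning is compared to the
  default with a 0.01 macro-F1 allowance.
* PLS-DA's one-hot/argmax construction ignores class imbalance.
* Shapley attributions are estimated for the model, not for the biology;
  dependence thresholds on observational data do not establish causal
  content targets.
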