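# Methods

## The problem

Distinguishing malignant from benign thyroid nodules from routine
clinical and ultrasound variables is a binary classification task on a
small, moderately imbalanced tabular cohort (~2:1
malignant:benign). Off-the-shelf classifiers leave accuracy on the
table in two places: hyperparameters left at library defaults, and
irrelevant or redundant predictors diluting the signal. `nmrtune`
treats both as a single continuous optimization problem and solves it
with a naked mole-rat (NMR) population metaheuristic.

## The optimizer

The NMR algorithm maintains `pop_size` candidate solutions ("individuals")
in a bounded box. Each generation the population is sorted by fitness and
split into a breeder fraction (default 1/5) and workers:

- **Breeders** exploit: with breeding probability `pb` (default 0.75) a
  breeder `b` moves to the per-dimension convex combination
  `(1-λ)·b + λ·best`, `λ ~ U(0,1)`; otherwise it takes a Lévy excursion
  `b + s·L·(b - best)` with `L` a Lévy(β) draw per dimension (Mantegna
  construction, β = 1.5 by default, scale `s` = 1% of each dimension's
  range). The heavy α-stable tail produces occasional long jumps that
  the Gaussian never would, protecting against premature convergence.
- **Workers** explore: `w + λ·(x_j - x_k)` with two random distinct
  population members, a differential move whose step statistics adapt to
  the population's spread.

Every candidate is then recombined with the global best by uniform
crossover with probability 0.5, mutated gene-wise with probability `pm`
(default 0.1, resampling the gene uniformly in its bounds), clamped to
the box, and accepted only if *strictly* fitter than the incumbent
(greedy, elitist; ties keep the incumbent for stability). Best-so-far
fitness is therefore monotone by construction.

**Determinism.** Every candidate draws from an RNG stream keyed by
`(seed, epoch, slot)`, so the trajectory is bit-identical however many
parallel workers evaluate fitness. Candidates whose decoded
configuration the classifier backend rejects receive a sentinel-worst
fitness (−∞) and are logged, never raised: a metaheuristic over a mixed
hyperparameter space must tolerate invalid decodings (e.g. a
solver/penalty pair the backend refuses). Such combinations are *not*
repaired — repair would bias the search space.

## Genome encoding

A candidate is a real vector. Categorical hyperparameters map half-open
unit bins to labels (`[0,1)` → first label, `[1,2)` → second, ...; the
top edge clamps to the last label so decoding is total on the closed
box). Integers are cast by truncation over `[lo, hi+1)`, which gives
every integer equal measure. Real genes pass through; multiplicative
ranges (learning rates, regularization strengths, `C`) are encoded as
log10 and exponentiated on decode. In 2-level mode the vector is
extended by one slot per dataset feature: `[0, 0.5)` excludes,
`[0.5, 1]` includes. An all-excluded mask is repaired by force-including
the argmax slot, keeping the fitness landscape smooth instead of
introducing an infeasible region.

Decoding is deterministic and piecewise constant, which the search
exploits by memoising fitness per decoded configuration.

The per-classifier gene lists follow the standard parameter sets of the
ten supported backends (decision tree, extra tree, gradient boosting,
KNN, LightGBM, logistic regression, NuSVM, random forest, XGBoost,
extra trees). Numeric ranges ship in a versioned registry
(`nmrtune.codec.DEFAULT_REGISTRY`, exportable to JSON) and every range
is overridable per run. Ranges were chosen as a practitioner would set
up a tuning study: wide enough to matter, excluding regions that
degenerate the model class (e.g. `min_weight_fraction_leaf` is capped
well below 0.5, where trees collapse to stumps regardless of the other
genes). Category order is part of the format contract — the bin mapping
depends on it.

## Fitness: cross-validated accuracy

Fitness of a decoded configuration is its pooled out-of-fold accuracy
under a stratified k-fold plan (default k = 10; class ratios per fold
within one sample of global). The plan is frozen per run so fitness is
deterministic per genome. Per fold, the z-score standardizer is fitted
on training rows only (a leakage-free default; a `global` mode that
standardizes before splitting is provided for pipelines that do so), the
optional oversampler augments training rows only, the backend is fitted,
and held-out predictions are pooled so each sample is predicted exactly
once. Accuracy, precision, recall and F1 come from the pooled confusion
counts (precision/recall defined as 0 on an empty denominator); AUC is
the Mann–Whitney rank statistic — the probability a random positive
outscores a random negative, ties counted half — which equals
trapezoidal ROC integration.

In 2-level mode, exact accuracy ties are broken toward fewer features by
a 1e-9 per-feature fitness discount — far below the 1/n accuracy
quantum, so it can never flip a genuine accuracy difference.

## Oversampling

SMOTE interpolates new minority rows `x_i + u·(x_nn - x_i)` between a
uniformly chosen minority parent and one of its k = 5 nearest minority
neighbours until the minority:majority ratio reaches `target_ratio`
(default 1). ADASYN allocates the synthetic budget
`G = (majority - minority)·target_ratio` proportionally to each minority
point's boundary weight r_i (fraction of majority members among its k
nearest neighbours over all classes), with largest-remainder rounding so
exactly G rows are generated; when no minority point touches the
boundary the allocation falls back to uniform (logged). Neighbour
searches run on z-scored features; interpolation happens in the original
space, so every synthetic row is a convex combination of two real
minority rows. Original rows are always preserved and held-out folds are
never touched.

## Shapley explanations

Attributions use marginal (interventional) imputation: the value of a
coalition S is the mean model score over a background sample with the
features in S pinned to the explained instance. For p ≤ 12 features the
values are computed exactly over all 2^p coalitions; otherwise by
permutation sampling (walk a random feature order, switching features
one at a time from a sampled background row to the instance; one
vectorised model call per permutation). The explained score is the
predicted malignant-class probability; the default background is 100
training rows. Exact mode satisfies efficiency, symmetry, dummy and
linearity; the MC estimator is unbiased and its efficiency residual
shrinks as permutations accumulate. Global importance is mean |value|
per feature, ranked with stable ties.

## Synthetic data

The generator emulates the thyroid-cohort schema: 18 predictors (age,
binary ultrasound findings, small-cardinality categoricals, log-normal
laboratory titres whose mean far exceeds the median) and a malignant
prevalence of 0.6648 (819:413). Labels come from a logistic model over
a configurable relevant-feature set (defaults: calcification,
multilaterality, shape, margin, composition with log-odds 1.3–0.6 on the
z-scored feature, logit noise SD 0.5), with the intercept calibrated by
bisection so the expected prevalence hits the target; all other features
are independent of the label. What this does *not* emulate: the real
cohort's inter-feature correlation structure, measurement error, or any
nonlinear physiology — so passing tests demonstrate that the machinery
(search, selection, metrics, oversampling) behaves correctly, not that
any particular accuracy transfers to real patients.
`planted_recovery_fixture` plants a known relevance mask in i.i.d.
Gaussian features so feature-selection recovery can be scored exactly.

## Problem sizes and numerical choices

The full-scale configuration (pop 1000 × 200 epochs × 10-fold CV per
fitness call) is cluster-scale and is available unchanged;
the shipped examples, tests and the acceptance script run desk-scale
analogues chosen to preserve the qualitative findings: cohorts of
350–1232 rows, 5-fold CV, populations of 12–30 over 10–100 epochs, and
registry overrides capping ensemble sizes at 20–80 trees. Benchmarks
(sphere, Rastrigin, Rosenbrock) exercise the optimizer without
classifiers in the loop. Other numerical conventions: bounds are
enforced by clamping (not reflection); breeder count is
`ceil(breeder_fraction · pop_size)` with stable sorting so ties keep
earlier individuals; Lévy scale defaults to 1% of each dimension's
range; single-class training folds and one-class AUC inputs are
evaluation failures, not silent zeros.

## Known limitations

- No nested CV: the reported best accuracy is the quantity the search
  maximised, hence optimistically biased as a generalisation estimate;
  a fully unbiased estimate would require nested CV.
- Conditional search spaces (genes activating other genes) are not
  modelled; invalid combinations are searched and rejected at fit time.
- Binary classification only; multi-class metrics are out of scope.
- The LightGBM gene list carries booster-alias names; the adapter
  resolves them with booster-native precedence and ignores
  `eval_metric`, which has no effect without a validation set.
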