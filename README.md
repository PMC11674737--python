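# nmrtune

Naked mole-rat metaheuristic optimization of classifiers for thyroid
nodule malignancy prediction: joint hyperparameter tuning and wrapper
feature selection with cross-validated fitness, SMOTE/ADASYN
oversampling stages, and Shapley-value explainability.

## Who this is for

Researchers building diagnostic classifiers on small clinical tabular
cohorts — here the motivating task is predicting whether a thyroid
nodule is malignant (`Mal` = 1) or benign from 18 clinical and
ultrasound predictors — who want a single search procedure that tunes a
classifier's hyperparameters and, optionally, selects the feature
subset at the same time.

## The method

A candidate solution ("individual") is a real vector **x** ∈ ∏ᵢ [lᵢ, uᵢ].
Intervals of each coordinate decode to hyperparameter values: a
K-category parameter maps `[0,1) → first label, …, [K−1, K) → last`; an
integer parameter is cast by truncation over `[lo, hi+1)`; real
parameters pass through (log₁₀-encoded for multiplicative ranges). In
**2-level mode** the vector gains one slot per feature: `[0, 0.5)`
excludes the feature, `[0.5, 1]` includes it.

The naked mole-rat (NMR) algorithm evolves a population of such vectors.
Each generation, the fittest fraction are *breeders*: with breeding
probability p_b = 0.75 a breeder moves along `(1−λ)·b + λ·best`
(λ ~ U(0,1) per dimension), otherwise it takes a heavy-tailed Lévy
excursion `b + s·L·(b − best)`, L ~ Lévy(β = 1.5) via the Mantegna
generator. The remaining *workers* make differential moves
`w + λ·(x_j − x_k)`. Candidates are recombined with the global best by
uniform crossover, mutated gene-wise with probability p_m = 0.1, clamped,
and accepted only if strictly fitter (greedy elitism — best-so-far
fitness is monotone).

Fitness is the pooled out-of-fold **accuracy** under a frozen stratified
k-fold plan: per fold, standardize on training rows, optionally
oversample training rows (SMOTE or ADASYN), fit the backend, score the
held-out rows; pool all held-out predictions into one confusion matrix.
Precision, recall, F1 = 2TP/(2TP+FP+FN) and the Mann–Whitney AUC are
reported alongside. Ten classifier backends are supported: decision
tree, extra tree, gradient boosting, KNN, LightGBM, logistic regression,
NuSVM, random forest, XGBoost, extra trees.

See `docs/methods.md` for the full model description, parameter
defaults, and limitations.

## Worked example

Generate a synthetic thyroid-like cohort (same schema as the real data:
18 predictors, binary `Mal` label, ~2:1 malignant prevalence, with a
known planted signal in calcification, multilaterality, shape, margin
and composition), then run the 2-level optimizer on LightGBM:

```bash
nmrtune generate-data thyroid_synth.csv --n 400 --seed 7
# wrote 400 rows x 18 features (malignant fraction 0.6500) to thyroid_synth.csv

nmrtune optimize thyroid_synth.csv --level 2 --classifier lightgbm \
    --cv 5 --pop-size 12 --epochs 10 --seed 1 --out-dir run2
# Classifier  Number of Features  Accuracy  F1-Score    AUC  Recall  Precision
#   lightgbm                  12    0.8225    0.8725 0.8456  0.9346     0.8182
```

The row reports pooled 5-fold cross-validated metrics of the best
genome found: 82.25% accuracy using 12 of the 18 features.
`run2/best_configs.json` holds the decoded winner — its selected
feature list (here including the planted signals Calcification,
Multilateral, Shape and Margin) and hyperparameters such as
`n_estimators: 251, max_depth: 2, learning_rate: 0.184`;
`run2/manifest.json` records every seed and the registry version for
reproduction.

The same search is available as a scikit-learn-style estimator:

```python
from nmrtune import NMRSearchCV

search = NMRSearchCV(classifier="lightgbm", select_features=True,
                     pop_size=12, epochs=10, cv=5, random_state=1)
search.fit(X, y)
search.best_score_      # pooled CV accuracy of the best genome
search.best_params_     # decoded hyperparameters
search.support_         # boolean feature mask
search.predict(X_new)   # best configuration refitted on all data
```

Other commands: `nmrtune evaluate` (library-default baselines),
`nmrtune optimize --level 1` (hyperparameters only),
`--oversample smote|adasyn`, `nmrtune explain` (Shapley importance
table), `nmrtune report`.

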