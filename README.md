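# radwise

Rank-weighted ensemble feature selection for high-dimensional omic panels.

Serum proteomic assays routinely quantify thousands of protein targets per
sample, while studies of treatment response often enroll fewer than a
hundred patients. Selecting a small, *named* panel of discriminative
features from such data is hard for two reasons: single selectors are
unstable across cross-validation folds (every fold yields a different
list), and univariate screens keep whole blocks of mutually redundant
correlated targets. `radwise` implements a hybrid selection procedure
aimed at paired pre-/post-treatment designs (label 0 = pre, 1 = post)
that addresses both.

## Method

Two complementary selectors run inside every fold of a *k*-fold split
(default *k* = 5), each fitted on the training samples only:

- **mRMR** — greedy forward selection maximizing, for a candidate
  feature X_i against the class Y and the already-selected set S,

  f(X_i) = relevance(Y, X_i) − (1/|S|) · Σ_{X_s ∈ S} redundancy(X_s, X_i)

  selecting ⌈log₂ p⌉ features per fold (13 for a 7,289-feature panel).
  On continuous abundances the default estimators are the ANOVA
  F statistic (relevance) and |Pearson r| (redundancy); a strict
  discrete mutual-information mode I(Y,X) = Σ p(x,y) log p(x,y)/(p(x)p(y))
  with quantile binning is also provided.
- **LASSO** — β̂ = argmin_β ‖y − Xβ‖² + λ‖β‖₁ on standardized features
  with the 0/1 label as numeric response; λ chosen by internal 10-fold
  cross-validation over a geometric grid; the selected features are those
  with β̂_j ≠ 0.

Each time a selector picks a feature, the feature's integer weight grows
by the selector's rank weight — 2 for mRMR, 1 for LASSO, the ranking their
standalone accuracies induce (re-derivable per dataset with
`rank_fs_methods` / `--auto-rank`). With 5 folds the attainable weights
span 0–15. Every minimum-weight threshold w_min = 15…1 induces a nested
candidate subset; each is scored by cross-validated classification with
five fixed-hyperparameter models (RBF-SVM, logistic regression, 5-NN,
random forest, AdaBoost) on six metrics (ACC, F1, AUC, precision, recall,
specificity). The final subset maximizes mean accuracy, breaking ties
toward fewer features, then the larger threshold.

Because the sweep reuses the selection folds (the protocol this package
reproduces), its reported accuracy is optimistic; `nested_cv_estimate`
wraps the whole pipeline in an outer cross-validation for a leakage-free
estimate. See `docs/methods.md`.

## Worked example

Generate a synthetic paired panel (30 patients → 60 samples, 200
features, 5 informative ones shifted by 0.8 in log-abundance after
treatment, each with 2 correlated proxies) and run the pipeline:

```sh
radwise synth --patients 30 --features 200 --informative 5 --seed 7 --out panel.csv
radwise run --input panel.csv --label-col label --patient-col patient_id \
            --seed 0 --out report.json
```

From `report.json`:

```
w_max 15
chosen w_min 3  classifier svm  n_features 15
features ['F0014', 'F0165', 'F0173', 'F0159', 'F0004', 'F0013', 'F0002',
          'F0006', 'F0169', 'F0009', 'F0012', 'F0034', 'F0042', 'F0103', 'F0122']
ACC 0.867  AUC 0.889
```

The maximum attainable weight is 15 (5 folds × weights 2+1). The best
mean accuracy (86.7%) occurred at minimum weight 3 with 15 features; the
planted signal F0002 and F0004 appear directly and the remaining planted
features through their correlated proxies (F0006, F0009, F0012–F0014 —
the ground-truth sidecar `panel.csv.truth.json` maps proxies to parents).
The report also stores the full (threshold × classifier) metric grid and
the configuration used; identical inputs and seed reproduce it
byte-for-byte.

The same machinery is available as a scikit-learn selector:

```python
from radwise import RadWise
model = RadWise(seed=0).fit(X, y, feature_names=names)
model.selected_features_   # the chosen panel
X_small = model.transform(X)
```

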