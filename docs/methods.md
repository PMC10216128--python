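# Methods

## The selection procedure

`radwise` targets paired pre-/post-intervention omic panels: n samples
(two per patient), p ≫ n features holding already-normalized positive
abundance values, and a binary label (0 = pre, 1 = post). The package
performs no normalization or calibration of its own and rejects missing
values at load time rather than imputing — assay panels of this kind are
delivered complete and normalized, and silent imputation would be a
change of data provenance the user never asked for.

The procedure has three phases.

**Phase 1 — per-fold selection.** The samples are split into k folds
(default 5, stratified; optional patient-grouped splitting keeps a
patient's pre/post pair in one fold). In each fold, two selectors are fit
on the training samples only:

- *mRMR* (greedy forward): criterion
  `f(X_i) = relevance(Y, X_i) − mean_{s ∈ S} redundancy(X_s, X_i)`, with
  the redundancy term 0 while S is empty, selecting
  `k = ⌈log₂ p⌉` features (minimum 1). Ties go to the lowest column
  index, making the ranking deterministic.
- *LASSO*: squared-error L1 fit of the 0/1 label on standardized
  features; the penalty is picked by internal 10-fold CV over a
  100-point geometric grid spanning [λ_max, 10⁻³ λ_max]; "selected"
  means a coefficient the coordinate-descent solver leaves exactly
  nonzero. The internal CV seed is the pipeline seed plus the fold index,
  so folds are decoupled but reproducible. An L1-penalized logistic
  variant exists behind a flag; the linear fit is the default because it
  is the form the procedure is defined with.

**Phase 2 — rank-based weighting.** Each feature's integer weight grows
by the selector's weight each time that selector picks it: mRMR 2,
LASSO 1 by default. These defaults encode the ranking the two selectors
earn by standalone accuracy on data of this kind; `rank_fs_methods`
re-derives them on any dataset (best selector gets weight |methods|,
worst 1; ties break by smaller mean selected-set size, then registration
order). With 5 folds and weights {2, 1} the weights span 0–15, and the
sum of all weights always equals Σ over (fold, method) of
weight × |selection| — a conservation law the tests enforce.

**Phase 3 — threshold sweep.** Every minimum weight w_min from
w_max down to 1 induces the candidate set {features with weight ≥ w_min}.
The sets are nested, so consecutive thresholds often repeat a set; its
metrics are computed once and reused. Each non-empty candidate is scored
by k-fold cross-validation with five classifiers, and the final choice
maximizes mean accuracy with ties broken toward fewer features, then the
larger threshold, then classifier registration order — a total order, so
the choice is independent of grid insertion order.

## Estimating mutual information on continuous abundances

The mRMR criterion is defined with discrete mutual information, but
protein abundances are continuous. The default estimator pair is the
one-way ANOVA F statistic (relevance) and the absolute Pearson
correlation (redundancy), combined subtractively as in the criterion's
difference form; a strict discrete mode (per-feature quantile binning
into `n_bins` = 10 bins, natural log by default, base 2 available) is
provided and is the mode verified against exhaustive step-wise oracles
in the tests. The two terms of the F-statistic mode live on different
scales (F is unbounded, |r| ≤ 1), so redundancy acts as a tie-breaker
among similarly relevant features rather than a hard veto; the discrete
mode penalizes duplicates at full strength (an exact copy loses its
entire relevance). Constant features get relevance 0 and are never
selected ahead of any informative feature.

## Classifiers and metrics

The five evaluation models are deliberately fixed, not tuned: RBF-kernel
SVM (C = 1, gamma scaled), L2 logistic regression (C = 1, tol 1e-4),
5-nearest-neighbors (Minkowski, uniform weights), 100-tree Gini random
forest (unlimited depth), and 50-stage AdaBoost (learning rate 1.0, the
SAMME algorithm of current scikit-learn; the real-valued SAMME.R variant
was retired upstream). All random states derive from the pipeline seed
(default 0). The margin and logistic models see per-fold standardized
features (scaler fit on the training rows only); neighbors, forest and
boosting consume raw values. Logistic regression runs with max_iter
raised to 1000 so the fixed protocol converges on standardized data
without warnings; the optimum is unchanged.

Metrics: ACC = (TP+TN)/total, PRE = TP/(TP+FP), REC = TP/(TP+FN),
SPEC = TN/(TN+FP), F1 = harmonic mean of PRE and REC, and AUC via the
Mann–Whitney rank statistic with midranks (equal to the trapezoidal ROC
area, invariant under monotone score transforms; probability scores when
the model exposes them, decision margins otherwise). A metric with a
zero denominator in a fold is *undefined* for that fold — reported as
NaN, excluded from the mean with a warning, never coerced to 0. Fold
aggregates are mean ± population standard deviation (ddof = 0; a
switchable choice, documented because either convention appears in the
field).

## The single-CV protocol and its optimism

By default the sweep evaluates candidates on the *same* folds used for
selection. This mirrors the single-5-fold protocol the procedure is
defined with, and it leaks: each test fold's samples sat in the training
data of the other folds' selector runs, and the final (w_min, classifier)
cell is itself chosen to maximize the evaluated accuracy. On
high-dimensional panels this optimism is large — on a 1000-feature panel
with *no* planted signal the protocol happily reports ~85% accuracy for
its chosen subset. `nested_cv_estimate` therefore wraps the entire
pipeline (selection, weighting, sweep, final choice) in an outer
cross-validation: for each outer fold the pipeline runs on the
outer-training samples only and its chosen subset + classifier are scored
once on the held-out fold. On the same null panel this estimate is
statistically indistinguishable from 50%. Reported single-CV accuracies
should be read as the protocol's internal score, not as generalization
estimates; the nested estimate is the honest one.

A related consequence: because the optimism grows with candidate-set
size, on panels whose true per-feature effects are moderate the
accuracy-maximizing threshold tends toward w_min = 1 and the chosen set
stays large. Strong planted effects (or real panels with strong
biomarkers) instead peak at high thresholds with few features.

## The synthetic generator

`SyntheticSpec` emulates a paired pre/post serum cohort. Defaults:
82 patients (164 samples), 1000 features (scalable to full panel size),
8 informative features, log-space post-treatment shift δ = 0.8,
2 correlated proxies per informative feature at ρ = 0.9, base
log-abundance mean 8 and sd 1 (RFU-like positive values after
exponentiation), and a per-sample multiplicative jitter of sd 0.05
mimicking residual scale variation after assay normalization. Features
are log-normal; informative features gain δ in post samples; each proxy
is built from its parent's standardized log signal
(ρ·parent + √(1−ρ²)·noise), so it inherits an attenuated shift exactly
as a correlated co-regulated protein would; the remaining features are
independent noise. Ground truth (informative names, proxy → parent map)
is returned separately and never enters the pipeline's input.

What the generator does *not* emulate: batch/plate effects, heavy-tailed
outliers, feature-wise variance heterogeneity, block correlation among
noise features, or multiple aptamers per protein. Tests passing on these
panels therefore demonstrate the machinery's correctness and the
procedure's qualitative behavior (signal recovery, redundancy handling,
selection optimism), not clinical performance.

## Numerical and degenerate-input choices

- Mutual information uses 0·log(0/·) = 0 and clips −0.0 to 0;
  an all-zero contingency table is a domain error.
- Candidate sets are ordered (weight descending, name ascending);
  an empty candidate set is valid and silently skipped by the sweep.
- λ_max in the LASSO grid is the smallest penalty zeroing every
  coefficient; "nonzero" is exact (coordinate descent returns exact
  zeros).
- Single-class inputs, k > p, weights outside [1, w_max], unpaired
  patients in the fold-change baseline, and selected names absent from
  the table all raise early with named diagnostics.
- Reports serialize with sorted keys and fixed indentation; NaN becomes
  JSON null. Identical inputs and seed give byte-identical files.

## Problem sizes used in the test suite

Unit tests run on panels of 20–40 patients and 30–200 features; the
recovery and null-behavior suites run the full default generator
(82 patients × 1000 features) across 5 seeds and one nested-CV null run
respectively — sizes chosen so the complete suite exercises the default
study shape while staying comfortably runnable on a single CPU.

## Known limitations

- The fold-change heuristic baseline (post/pre ratio exceeding a
  threshold in a minimum fraction of patients) requires exactly one
  pre and one post sample per patient; its two thresholds are mandatory
  because no universal defaults exist.
- The F-statistic mRMR mode's scale mismatch (see above) weakens
  redundancy pruning relative to the discrete mode.
- Aptamers mapping to the same protein are treated as independent
  features.
- The single-CV protocol's reported accuracy is optimistic by
  construction; use `nested_cv_estimate` for generalization claims.
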