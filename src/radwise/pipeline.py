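"""The RadWise estimator: hybrid rank-weighted ensemble feature selection.

Two selectors — greedy mRMR and cross-validated LASSO — are run inside
every fold of a k-fold split of the data.  Each time a selector picks a
feature, the feature's integer weight grows by the selector's rank weight
(mRMR 2, LASSO 1 by default).  Every minimum-weight threshold from
k_folds × Σ weights down to 1 then induces a candidate subset, each
candidate is scored by cross-validated classification, and the final
subset is the smallest one attaining the best mean accuracy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .evaluation import DEFAULT_CLASSIFIERS, ClassifierSpec
from .io import FeatureTable
from .sweep import SweepResult, evaluate_no_fs_baseline, sweep_min_weights
from .weighting import (DEFAULT_METHOD_WEIGHTS, MethodRank, accumulate_weights,
                        collect_fold_selections, plan_folds, rank_fs_methods)

__all__ = ["RadWise", "RunConfig", "run_radwise", "nested_cv_estimate"]


class RadWise(SelectorMixin, BaseEstimator):
    """Rank-weighted ensemble feature selector (mRMR + LASSO).

    Parameters
    ----------
    n_folds : int, default 5
        Folds for both the selection/weighting phase and the evaluation
        sweep (the same plan is reused unless ``nested_cv``).
    seed : int, default 0
        Master seed: fold shuffling, per-fold LASSO alpha CV (offset by
        fold index) and classifier randomness all derive from it.
    method_weights : dict or None
        Selector rank weights; None uses {"mrmr": 2, "lasso": 1}.
    auto_rank_methods : bool, default False
        Re-derive the weights from standalone selector accuracy on this
        dataset instead of using ``method_weights``.
    mrmr_k : int or "auto"
        Features per fold for mRMR; "auto" is ceil(log2(p)).
    lasso_cv_folds : int, default 10
        Internal folds for the LASSO penalty search.
    classifiers : sequence of str or None
        Classifier ids to sweep; None means all five registered ones
        (svm, lr, knn, rf, adaboost).
    stratified, group_by_patient : bool
        Fold-plan options; grouping requires patient ids at fit time.
    selector_configs : dict or None
        Extra keyword arguments per selector id, e.g.
        ``{"mrmr": {"relevance": "discrete-mi"}}``.

    Attributes
    ----------
    weight_table_ : WeightTable
        Accumulated per-feature integer weights with provenance.
    sweep_result_ : SweepResult
        Full (threshold × classifier) metric grid and the chosen cell.
    selected_features_ : list of str
        Names of the final chosen subset.
    support_ : ndarray of bool
        Mask over input columns for :meth:`transform`.
    method_ranks_ : list of MethodRank
        The selector weights actually applied.

    Examples
    --------
    >>> from radwise.synth import SyntheticSpec, generate_dataset
    >>> table, truth = generate_dataset(SyntheticSpec(seed=0, n_features=60))
    >>> model = RadWise(seed=0).fit(table.values, table.labels,
    ...                             feature_names=table.feature_names)
    >>> len(model.selected_features_) <= 60
    True
    """

    def __init__(self, n_folds=5, seed=0, method_weights=None,
                 auto_rank_methods=False, mrmr_k="auto", lasso_cv_folds=10,
                 classifiers=None, stratified=True, group_by_patient=False,
                 selector_configs=None):
        self.n_folds = n_folds
        self.seed = seed
        self.method_weights = method_weights
        self.auto_rank_methods = auto_rank_methods
        self.mrmr_k = mrmr_k
        self.lasso_cv_folds = lasso_cv_folds
        self.classifiers = classifiers
        self.stratified = stratified
        self.group_by_patient = group_by_patient
        self.selector_configs = selector_configs

    # -- internals ---------------------------------------------------------

    def _selector_configs(self):
        cfg = {"mrmr": {"k": self.mrmr_k},
               "lasso": {"cv_folds": self.lasso_cv_folds}}
        for mid, extra in (self.selector_configs or {}).items():
            cfg.setdefault(mid, {}).update(extra)
        return cfg

    def _classifier_specs(self):
        ids = list(self.classifiers) if self.classifiers else list(DEFAULT_CLASSIFIERS)
        return [ClassifierSpec(id=cid, seed=self.seed) for cid in ids]

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, feature_names=None, patient_ids=None):
        """Run selection, weighting and the threshold sweep on (X, y)."""
        X, y = validate_data(self, X, y)
        if feature_names is None:
            feature_names = getattr(
                self, "feature_names_in_",
                np.array([f"x{j}" for j in range(X.shape[1])]))
        table = FeatureTable(
            values=X,
            feature_names=list(feature_names),
            sample_ids=[f"s{i}" for i in range(X.shape[0])],
            labels=np.asarray(y, dtype=int),
            patient_ids=list(patient_ids) if patient_ids is not None else None,
        )
        plan = plan_folds(table, k_folds=self.n_folds,
                          stratified=self.stratified,
                          group_by_patient=self.group_by_patient,
                          seed=self.seed)
        cfg = self._selector_configs()
        if self.auto_rank_methods:
            ranks = rank_fs_methods(
                table, plan,
                list(self.method_weights or DEFAULT_METHOD_WEIGHTS),
                seed=self.seed, selector_configs=cfg)
        else:
            weights = self.method_weights or DEFAULT_METHOD_WEIGHTS
            ranks = [MethodRank(method_id=m, weight=w)
                     for m, w in weights.items()]
        selections = collect_fold_selections(table, plan, ranks, cfg,
                                             seed=self.seed)
        weight_table = accumulate_weights(selections, ranks,
                                          feature_names=table.feature_names)
        # The sweep reuses the selection folds (the single-CV protocol);
        # nested_cv_estimate provides the leakage-free alternative.
        result = sweep_min_weights(table, weight_table,
                                   self._classifier_specs(), plan)

        self.fold_plan_ = plan
        self.method_ranks_ = ranks
        self.weight_table_ = weight_table
        self.sweep_result_ = result
        self.selected_features_ = list(result.chosen_set.features)
        self.chosen_w_min_ = result.chosen_w_min
        self.chosen_classifier_ = result.chosen_classifier
        self.w_max_ = weight_table.w_max
        sel = set(self.selected_features_)
        self.support_ = np.array([f in sel for f in table.feature_names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


def nested_cv_estimate(table: FeatureTable, estimator: RadWise | None = None,
                       n_outer_folds: int = 5, seed: int = 0) -> dict:
    """Leakage-free accuracy of the whole selection procedure.

    The single-CV protocol reuses the selection folds for the threshold
    sweep, so every feature was picked while the evaluation samples were
    visible to most selector runs — its reported accuracy is optimistic,
    severely so on high-dimensional panels.  This estimator wraps the
    *entire* pipeline (selection, weighting, sweep, final choice) in an
    outer cross-validation: for each outer fold the pipeline runs on the
    outer-training samples only, and its chosen subset + classifier are
    scored once on the held-out outer fold.

    Returns per-outer-fold accuracies, their mean ± population std, and
    the per-fold chosen subset sizes.
    """
    from .evaluation import build_classifier

    base = estimator if estimator is not None else RadWise(seed=seed)
    params = base.get_params()
    outer = plan_folds(table, k_folds=n_outer_folds,
                       stratified=params.get("stratified", True),
                       group_by_patient=params.get("group_by_patient", False),
                       seed=seed)
    accs, sizes, cells = [], [], []
    for train_idx, test_idx in outer.assignments:
        sub = table.subset_samples(train_idx)
        model = RadWise(**params).fit(
            sub.values, sub.labels, feature_names=sub.feature_names,
            patient_ids=sub.patient_ids)
        feats = model.selected_features_
        spec = ClassifierSpec(id=model.chosen_classifier_, seed=params["seed"])
        cols = [table.feature_names.index(f) for f in feats]
        clf = build_classifier(spec)
        clf.fit(table.values[np.ix_(train_idx, cols)], table.labels[train_idx])
        pred = clf.predict(table.values[np.ix_(test_idx, cols)])
        accs.append(float((pred == table.labels[test_idx]).mean()))
        sizes.append(len(feats))
        cells.append({"w_min": model.chosen_w_min_,
                      "classifier": model.chosen_classifier_})
    accs_arr = np.asarray(accs)
    return {
        "per_fold_accuracy": accs,
        "mean_accuracy": float(accs_arr.mean()),
        "std_accuracy": float(accs_arr.std()),
        "chosen_sizes": sizes,
        "chosen_cells": cells,
        "n_outer_folds": n_outer_folds,
        "seed": seed,
    }


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (CLI / YAML surface).

    All defaults mirror the estimator's: 5 folds, seed 0, method weights
    mrmr=2 / lasso=1, auto mRMR k, 10-fold LASSO alpha CV, all five
    classifiers.
    """

    input: str | None = None
    label_column: str = "label"
    label_map: dict[str, int] | None = None
    orientation: str = "rows-are-samples"
    patient_column: str | None = None
    filter_human: bool = False
    folds: int = 5
    seed: int = 0
    method_weights: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_WEIGHTS))
    auto_rank_methods: bool = False
    mrmr_k: int | str = "auto"
    lasso_cv_folds: int = 10
    classifiers: list[str] = field(
        default_factory=lambda: list(DEFAULT_CLASSIFIERS))
    stratified: bool = True
    group_by_patient: bool = False
    nested_cv: bool = False
    no_fs_baseline: bool = False
    osth_fold_change: float | None = None
    osth_patient_fraction: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def run_radwise(table: FeatureTable, config: RunConfig) -> tuple[RadWise, SweepResult]:
    """Execute the full pipeline on a FeatureTable under a RunConfig."""
    from .io import filter_human_features
    from .sweep import heuristic_baseline_select

    if config.filter_human:
        table = filter_human_features(table)
    model = RadWise(
        n_folds=config.folds, seed=config.seed,
        method_weights=config.method_weights,
        auto_rank_methods=config.auto_rank_methods,
        mrmr_k=config.mrmr_k, lasso_cv_folds=config.lasso_cv_folds,
        classifiers=config.classifiers, stratified=config.stratified,
        group_by_patient=config.group_by_patient,
    )
    model.fit(table.values, table.labels, feature_names=table.feature_names,
              patient_ids=table.patient_ids)
    result = model.sweep_result_
    if config.nested_cv:
        result.baselines["nested_cv"] = nested_cv_estimate(
            table, model, n_outer_folds=config.folds, seed=config.seed)
    if config.no_fs_baseline:
        base = evaluate_no_fs_baseline(table, model._classifier_specs(),
                                       model.fold_plan_)
        result.baselines["no_fs"] = base
    if config.osth_fold_change is not None:
        if config.osth_patient_fraction is None:
            raise ValueError("OSTH baseline needs both the fold-change "
                             "threshold and the patient fraction")
        result.baselines["osth"] = {
            "fold_change_threshold": config.osth_fold_change,
            "min_patient_fraction": config.osth_patient_fraction,
            "selected_features": heuristic_baseline_select(
                table, config.osth_fold_change, config.osth_patient_fraction),
        }
    return model, result
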