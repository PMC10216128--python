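"""Fold planning, per-fold selector runs, and rank-based weight accumulation.

Each selector runs inside every cross-validation fold on the training rows
only; every time it picks a feature, that feature's integer weight grows by
the selector's rank weight (mRMR 2, LASSO 1 by default — the ranking the
standalone accuracy comparison produces).  With 5 folds and weights {2, 1}
the attainable weights span 0 (never picked) to 15 (picked by both
selectors in every fold).  Thresholding the accumulated weights at a
minimum value w_min induces nested candidate feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .evaluation import ClassifierSpec, evaluate_cv
from .selectors import LassoSelector, MRMRSelector

__all__ = [
    "FoldPlan",
    "MethodRank",
    "WeightTable",
    "CandidateSet",
    "FoldSelection",
    "DEFAULT_METHOD_WEIGHTS",
    "plan_folds",
    "collect_fold_selections",
    "accumulate_weights",
    "candidate_set",
    "rank_fs_methods",
]

DEFAULT_METHOD_WEIGHTS = {"mrmr": 2, "lasso": 1}


@dataclass
class FoldPlan:
    """A deterministic cross-validation partition of the samples."""

    k_folds: int
    assignments: list[tuple[np.ndarray, np.ndarray]]
    stratified: bool
    group_by_patient: bool
    seed: int


@dataclass(frozen=True)
class MethodRank:
    """A selector identity with its rank-derived integer weight."""

    method_id: str
    weight: int

    def __post_init__(self):
        if self.weight < 1:
            raise ValueError("method weight must be a positive integer")


@dataclass
class FoldSelection:
    """Features one selector picked in one fold (training rows only)."""

    fold: int
    method_id: str
    features: list[str]


@dataclass
class WeightTable:
    """Accumulated per-feature integer weights across folds and selectors.

    ``w_max = k_folds × Σ method weights`` is the weight of a feature every
    selector picks in every fold.  ``provenance`` maps (fold, method_id) to
    the selected feature list, so Σ weights always equals
    Σ over (fold, method) of weight × |selection| (conservation).
    """

    weights: dict[str, int]
    w_max: int
    provenance: dict[tuple[int, str], list[str]] = field(default_factory=dict)

    def nonzero(self) -> dict[str, int]:
        return {f: w for f, w in self.weights.items() if w > 0}


@dataclass
class CandidateSet:
    """The feature subset with accumulated weight >= w_min.

    Features are ordered by (weight descending, name ascending); raising
    w_min can only shrink the set (nesting).
    """

    w_min: int
    features: list[str]

    def __len__(self) -> int:
        return len(self.features)


def plan_folds(table, k_folds: int = 5, stratified: bool = True,
               group_by_patient: bool = False, seed: int = 0) -> FoldPlan:
    """Build a deterministic k-fold partition of the table's samples.

    Stratification keeps the class ratio of every test fold within one
    sample of the global ratio; ``group_by_patient`` additionally keeps all
    samples of a patient in the same fold (requires ``patient_ids``).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = table.n_samples
    if n < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} samples for {k_folds} folds")
    y = table.labels
    if stratified and min(np.bincount(y)) < k_folds:
        raise ValueError("each class needs at least k_folds samples "
                         "for stratified folding")
    if group_by_patient:
        if table.patient_ids is None:
            raise ValueError("group_by_patient requires patient_ids")
        groups = np.asarray(table.patient_ids)
        splitter = StratifiedGroupKFold(n_splits=k_folds, shuffle=True,
                                        random_state=seed)
        splits = splitter.split(table.values, y, groups)
    elif stratified:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True,
                                   random_state=seed)
        splits = splitter.split(table.values, y)
    else:
        rng = np.random.RandomState(seed)
        perm = rng.permutation(n)
        chunks = np.array_split(perm, k_folds)
        splits = ((np.setdiff1d(perm, c), np.sort(c)) for c in chunks)
    assignments = [(np.asarray(tr), np.asarray(te)) for tr, te in splits]
    return FoldPlan(k_folds=k_folds, assignments=assignments,
                    stratified=stratified, group_by_patient=group_by_patient,
                    seed=seed)


def _make_selector(method_id: str, n_features: int, configs: dict, seed: int,
                   fold: int):
    cfg = dict(configs.get(method_id, {}))
    if method_id == "mrmr":
        return MRMRSelector(**cfg)
    if method_id == "lasso":
        # per-fold seed offset decouples the internal alpha CV across folds
        cfg.setdefault("seed", seed + fold)
        return LassoSelector(**cfg)
    raise ValueError(f"unregistered selector {method_id!r}")


def collect_fold_selections(table, plan: FoldPlan, methods: list[MethodRank],
                            selector_configs: dict | None = None,
                            seed: int = 0) -> list[FoldSelection]:
    """Run every registered selector on every fold's training rows.

    Returns k_folds × |methods| selections; a selector failure is re-raised
    naming the fold and method it occurred in.
    """
    selector_configs = selector_configs or {}
    out: list[FoldSelection] = []
    for fold, (train_idx, _) in enumerate(plan.assignments):
        sub = table.subset_samples(train_idx)
        for method in methods:
            sel = _make_selector(method.method_id, table.n_features,
                                 selector_configs, seed, fold)
            try:
                sel.fit(sub.values, sub.labels)
            except Exception as exc:
                raise RuntimeError(
                    f"selector {method.method_id!r} failed on fold {fold}: {exc}"
                ) from exc
            mask = sel.get_support()
            names = [f for f, m in zip(table.feature_names, mask) if m]
            out.append(FoldSelection(fold=fold, method_id=method.method_id,
                                     features=names))
    return out


def accumulate_weights(selections: list[FoldSelection],
                       methods: list[MethodRank],
                       feature_names: list[str] | None = None) -> WeightTable:
    """Sum each feature's weight over every (fold, method) that selected it."""
    weight_of = {m.method_id: m.weight for m in methods}
    folds = sorted({s.fold for s in selections})
    w_max = len(folds) * sum(weight_of.values())
    known = set(feature_names) if feature_names is not None else None
    weights: dict[str, int] = (
        {f: 0 for f in feature_names} if feature_names is not None else {}
    )
    provenance: dict[tuple[int, str], list[str]] = {}
    for s in selections:
        if s.method_id not in weight_of:
            raise ValueError(f"selection from unregistered method {s.method_id!r}")
        provenance[(s.fold, s.method_id)] = list(s.features)
        for f in s.features:
            if known is not None and f not in known:
                raise ValueError(f"selected feature {f!r} not in the table")
            weights[f] = weights.get(f, 0) + weight_of[s.method_id]
    return WeightTable(weights=weights, w_max=w_max, provenance=provenance)


def candidate_set(weight_table: WeightTable, w_min: int) -> CandidateSet:
    """Features whose accumulated weight is at least ``w_min``."""
    if not 1 <= w_min <= weight_table.w_max:
        raise ValueError(f"w_min must be in [1, {weight_table.w_max}]")
    feats = [f for f, w in weight_table.weights.items() if w >= w_min]
    feats.sort(key=lambda f: (-weight_table.weights[f], f))
    return CandidateSet(w_min=w_min, features=feats)


def rank_fs_methods(table, plan: FoldPlan, candidate_methods: list[str],
                    ranking_classifier: str = "lr", seed: int = 0,
                    selector_configs: dict | None = None) -> list[MethodRank]:
    """Assign integer weights to selectors by standalone CV accuracy.

    Each selector is run alone (selection on training rows, evaluation of
    the induced subset with ``ranking_classifier``); methods are ranked by
    mean accuracy — best gets weight |methods|, worst gets 1.  Ties break
    by smaller mean selected-set size, then registration order.
    """
    if not candidate_methods:
        raise ValueError("at least one candidate method required")
    stats = []
    for order, method_id in enumerate(candidate_methods):
        probe = [MethodRank(method_id=method_id, weight=1)]
        selections = collect_fold_selections(table, plan, probe,
                                             selector_configs, seed=seed)
        accs, sizes = [], []
        for s in selections:
            if not s.features:
                continue
            test_idx = plan.assignments[s.fold][1]
            holdout = FoldPlan(
                k_folds=1, stratified=plan.stratified,
                group_by_patient=plan.group_by_patient, seed=plan.seed,
                assignments=[(plan.assignments[s.fold][0], test_idx)],
            )
            rep = evaluate_cv(table, s.features,
                              ClassifierSpec(id=ranking_classifier, seed=seed),
                              holdout)
            accs.append(rep.mean["ACC"])
            sizes.append(len(s.features))
        mean_acc = float(np.mean(accs)) if accs else 0.0
        mean_size = float(np.mean(sizes)) if sizes else float("inf")
        stats.append((method_id, mean_acc, mean_size, order))
    stats.sort(key=lambda t: (-t[1], t[2], t[3]))
    n = len(stats)
    return [MethodRank(method_id=mid, weight=n - rank)
            for rank, (mid, _, _, _) in enumerate(stats)]
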