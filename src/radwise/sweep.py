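"""Minimum-weight threshold sweep, final subset choice, and baselines.

Every integer threshold from w_max down to 1 induces a candidate feature
set; each non-empty set is evaluated with every registered classifier by
cross-validation.  Because the sets are nested, consecutive thresholds
often induce the same set — its metrics are computed once and reused.  The
final choice maximizes mean accuracy, breaking ties toward fewer features,
then toward the larger threshold, then classifier registration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import ClassifierSpec, MetricsReport, evaluate_cv
from .weighting import CandidateSet, FoldPlan, WeightTable, candidate_set

__all__ = [
    "GridCell",
    "SweepResult",
    "sweep_min_weights",
    "select_final",
    "heuristic_baseline_select",
    "evaluate_no_fs_baseline",
]


@dataclass
class GridCell:
    w_min: int
    classifier_id: str
    n_features: int
    metrics: MetricsReport


@dataclass
class SweepResult:
    """The (threshold × classifier) performance grid plus the chosen subset."""

    grid: list[GridCell]
    chosen_w_min: int
    chosen_classifier: str
    chosen_set: CandidateSet
    w_max: int
    classifier_order: list[str]
    baselines: dict = field(default_factory=dict)

    @property
    def chosen_metrics(self) -> MetricsReport:
        for cell in self.grid:
            if (cell.w_min == self.chosen_w_min
                    and cell.classifier_id == self.chosen_classifier):
                return cell.metrics
        raise LookupError("chosen cell missing from grid")

    def to_dict(self) -> dict:
        return {
            "w_max": self.w_max,
            "classifier_order": self.classifier_order,
            "chosen": {
                "w_min": self.chosen_w_min,
                "classifier": self.chosen_classifier,
                "n_features": len(self.chosen_set),
                "selected_features": list(self.chosen_set.features),
                "metrics": self.chosen_metrics.to_dict(),
            },
            "grid": [
                {"w_min": c.w_min, "classifier": c.classifier_id,
                 "n_features": c.n_features, "metrics": c.metrics.to_dict()}
                for c in self.grid
            ],
            "baselines": {
                k: ({kk: (vv.to_dict() if isinstance(vv, MetricsReport) else vv)
                     for kk, vv in v.items()} if isinstance(v, dict) else v)
                for k, v in self.baselines.items()
            },
        }

    def grid_frame(self):
        """Grid as a DataFrame: rows = w_min (with n_features), cols = classifiers."""
        import pandas as pd

        rows = {}
        for c in self.grid:
            key = (c.w_min, c.n_features)
            rows.setdefault(key, {})[c.classifier_id] = c.metrics.mean["ACC"]
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index = pd.MultiIndex.from_tuples(df.index,
                                             names=["w_min", "n_features"])
        return df.sort_index(ascending=[False, True])[self.classifier_order]


def sweep_min_weights(table, weight_table: WeightTable,
                      classifiers: list[ClassifierSpec],
                      plan: FoldPlan) -> SweepResult:
    """Evaluate every threshold w_max..1 against every classifier.

    Thresholds whose candidate set coincides with an already-evaluated set
    reuse its metrics; empty candidate sets are skipped.
    """
    if not weight_table.nonzero():
        raise ValueError("no feature has weight >= 1; nothing to sweep")
    grid: list[GridCell] = []
    cache: dict[tuple, dict[str, tuple[int, MetricsReport]]] = {}
    for w_min in range(weight_table.w_max, 0, -1):
        cand = candidate_set(weight_table, w_min)
        if not cand.features:
            continue
        key = tuple(cand.features)
        if key not in cache:
            cache[key] = {
                spec.id: (len(cand), evaluate_cv(table, cand.features, spec, plan))
                for spec in classifiers
            }
        for spec in classifiers:
            n_feat, metrics = cache[key][spec.id]
            grid.append(GridCell(w_min=w_min, classifier_id=spec.id,
                                 n_features=n_feat, metrics=metrics))
    order = [spec.id for spec in classifiers]
    w_min, cid = select_final(grid, order)
    return SweepResult(
        grid=grid, chosen_w_min=w_min, chosen_classifier=cid,
        chosen_set=candidate_set(weight_table, w_min),
        w_max=weight_table.w_max, classifier_order=order,
    )


def select_final(grid: list[GridCell],
                 classifier_order: list[str]) -> tuple[int, str]:
    """Lexicographic choice over the grid.

    Maximize mean accuracy; ties → fewest features, then largest w_min,
    then classifier registration order.  Insertion order of the grid never
    affects the result.
    """
    if not grid:
        raise ValueError("empty grid")
    pos = {cid: i for i, cid in enumerate(classifier_order)}

    def key(cell: GridCell):
        return (-cell.metrics.mean["ACC"], cell.n_features, -cell.w_min,
                pos.get(cell.classifier_id, len(pos)))

    best = min(grid, key=key)
    return best.w_min, best.classifier_id


def heuristic_baseline_select(table, fold_change_threshold: float,
                              min_patient_fraction: float) -> list[str]:
    """Fold-change screening baseline on paired pre/post samples.

    Selects the features whose post/pre abundance ratio exceeds
    ``fold_change_threshold`` in at least ``min_patient_fraction`` of the
    patients (e.g. threshold 1.5 captures >50% elevation after treatment).
    Unlike the redundancy-aware pipeline, correlated proxies of a shifted
    feature are all selected.
    """
    if fold_change_threshold <= 1:
        raise ValueError("fold_change_threshold must exceed 1")
    if not 0 < min_patient_fraction <= 1:
        raise ValueError("min_patient_fraction must be in (0, 1]")
    if table.patient_ids is None:
        raise ValueError("patient pairing (patient_ids) required")
    pre: dict[str, int] = {}
    post: dict[str, int] = {}
    for i, (pid, lab) in enumerate(zip(table.patient_ids, table.labels)):
        bucket = post if lab == 1 else pre
        if pid in bucket:
            raise ValueError(f"patient {pid!r} has more than one "
                             f"{'post' if lab == 1 else 'pre'} sample")
        bucket[pid] = i
    unpaired = sorted(set(pre) ^ set(post))
    if unpaired:
        raise ValueError(f"unpaired patients: {unpaired}")
    patients = sorted(pre)
    pre_m = table.values[[pre[p] for p in patients]]
    post_m = table.values[[post[p] for p in patients]]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = post_m / pre_m
    exceeds = (ratio > fold_change_threshold).mean(axis=0)
    return [f for f, frac in zip(table.feature_names, exceeds)
            if frac >= min_patient_fraction]


def evaluate_no_fs_baseline(table, classifiers: list[ClassifierSpec],
                            plan: FoldPlan) -> dict[str, dict]:
    """Cross-validated performance of every classifier on the full panel."""
    out = {}
    for spec in classifiers:
        rep = evaluate_cv(table, table.feature_names, spec, plan)
        out[spec.id] = {"n_features": table.n_features, "metrics": rep}
    return out
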