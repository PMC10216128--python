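"""Classifier registry, confusion-matrix metrics, and cross-validated scoring.

Six metrics are reported per classifier: accuracy, F1, AUC, precision,
recall (sensitivity) and specificity, each computed per fold and aggregated
as mean ± standard deviation across folds.  A metric whose denominator is
zero in a fold is *undefined* for that fold (not 0) and is excluded from
the aggregate with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ClassifierSpec",
    "DEFAULT_CLASSIFIERS",
    "build_classifier",
    "compute_metrics",
    "rank_auc",
    "evaluate_cv",
]

METRIC_NAMES = ("ACC", "F1", "AUC", "PRE", "REC", "SPEC")


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix cell counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Per-fold metric values with mean and std aggregates.

    ``per_fold[m]`` holds one value per fold (NaN where the metric was
    undefined in that fold); ``mean[m]`` / ``std[m]`` are aggregated over
    the defined folds only.  ACC, F1, PRE, REC, SPEC are fractions in
    [0, 1]; AUC is the rank-based ROC area.
    """

    per_fold: dict[str, list[float]] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_folds(cls, fold_values: list[dict[str, float]],
                   ddof: int = 0) -> "MetricsReport":
        rep = cls()
        for m in METRIC_NAMES:
            vals = [fv.get(m, float("nan")) for fv in fold_values]
            arr = np.asarray(vals, dtype=float)
            ok = ~np.isnan(arr)
            if not ok.all():
                warnings.warn(
                    f"metric {m} undefined in {int((~ok).sum())} fold(s); "
                    "excluded from the mean", stacklevel=2)
            rep.per_fold[m] = vals
            rep.mean[m] = float(arr[ok].mean()) if ok.any() else float("nan")
            rep.std[m] = (float(arr[ok].std(ddof=ddof))
                          if ok.sum() > ddof else float("nan"))
        return rep

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "mean": self.mean, "std": self.std}


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, F1, precision, recall and specificity from confusion counts.

    Zero-denominator metrics come back as NaN (undefined), distinct from 0.
    """
    if counts.total <= 0:
        raise ValueError("no evaluated samples")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    acc = (tp + tn) / counts.total
    pre = ratio(tp, tp + fp)
    rec = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    f1 = (2 * pre * rec / (pre + rec)
          if not (np.isnan(pre) or np.isnan(rec)) and (pre + rec) > 0
          else float("nan"))
    return {"ACC": acc, "F1": f1, "PRE": pre, "REC": rec, "SPEC": spec}


def rank_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Uses midranks for tied scores, making the value equal to the
    trapezoidal area under the empirical ROC curve.  Invariant under any
    strictly increasing transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class ClassifierSpec:
    """One of the five registered classifiers with its fixed hyperparameters.

    ``standardize`` controls per-fold feature standardization (fit on the
    training rows, applied to the test rows) before the model.
    """

    id: str
    seed: int = 0
    standardize: bool | None = None  # None -> registry default


# Registry defaults: RBF-kernel SVM (C=1), L2 logistic regression (C=1,
# tol 1e-4), 5-NN with Minkowski distance and uniform weights, 100-tree
# Gini random forest with unlimited depth, and 50-stage AdaBoost with
# learning rate 1.  The margin and logistic models see standardized
# features; neighbors, forest and boosting consume raw values.
DEFAULT_CLASSIFIERS = ("svm", "lr", "knn", "rf", "adaboost")
_STANDARDIZE_DEFAULT = {"svm": True, "lr": True, "knn": False,
                        "rf": False, "adaboost": False}


def build_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn estimator for a registered classifier id."""
    cid, seed = spec.id, spec.seed
    if cid == "svm":
        model = SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed)
    elif cid == "lr":
        # default penalty is ridge (L2); C=1 and tol=1e-4 are the sklearn
        # defaults, spelled out because they are part of the fixed protocol
        model = LogisticRegression(C=1.0, tol=1e-4, max_iter=1000,
                                   random_state=seed)
    elif cid == "knn":
        model = KNeighborsClassifier(n_neighbors=5, metric="minkowski",
                                     weights="uniform")
    elif cid == "rf":
        model = RandomForestClassifier(n_estimators=100, criterion="gini",
                                       max_depth=None, min_samples_split=2,
                                       min_samples_leaf=1, random_state=seed)
    elif cid == "adaboost":
        model = AdaBoostClassifier(n_estimators=50, learning_rate=1.0,
                                   random_state=seed)
    else:
        raise ValueError(f"unknown classifier id {cid!r}; "
                         f"registered: {DEFAULT_CLASSIFIERS}")
    standardize = (_STANDARDIZE_DEFAULT[cid] if spec.standardize is None
                   else spec.standardize)
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("model", model)])
    return model


def _continuous_scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, 1]
        except AttributeError:  # e.g. SVC without probability=True
            pass
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    warnings.warn("classifier exposes no continuous score; "
                  "AUC computed from hard 0/1 predictions", stacklevel=2)
    return model.predict(X).astype(float)


def evaluate_cv(table, feature_subset, classifier: ClassifierSpec, plan) -> MetricsReport:
    """Cross-validated evaluation of one classifier on one feature subset.

    For each fold of ``plan`` the classifier is fit on the training rows
    restricted to ``feature_subset`` and scored on the test rows; per-fold
    metrics are aggregated as mean ± population std across folds.
    """
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature subset is empty")
    sub = table.subset_features(feature_subset)
    X, y = sub.values, sub.labels
    fold_values = []
    for train_idx, test_idx in plan.assignments:
        model = build_classifier(classifier)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        y_test = y[test_idx]
        counts = ConfusionCounts(
            TP=int(((pred == 1) & (y_test == 1)).sum()),
            TN=int(((pred == 0) & (y_test == 0)).sum()),
            FP=int(((pred == 1) & (y_test == 0)).sum()),
            FN=int(((pred == 0) & (y_test == 1)).sum()),
        )
        metrics = compute_metrics(counts)
        metrics["AUC"] = rank_auc(_continuous_scores(model, X[test_idx]), y_test)
        fold_values.append(metrics)
    return MetricsReport.from_folds(fold_values)
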