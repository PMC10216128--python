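"""Base feature selectors: greedy mRMR and cross-validated LASSO.

The minimum-redundancy-maximum-relevance criterion for a candidate feature
X_i against the class Y and the already-selected set S is

    f(X_i) = relevance(Y, X_i) - (1/|S|) * sum_{X_s in S} redundancy(X_s, X_i)

with the redundancy term defined as 0 while S is empty.  On continuous
abundance data the default estimator pair is the one-way ANOVA F statistic
for relevance and the absolute Pearson correlation for redundancy, combined
in the subtractive form above; a strict discrete mutual-information mode
(quantile binning) is provided and is the one checked against exhaustive
oracles in the tests.

LASSO selection minimizes ||y - X beta||^2 + lambda * ||beta||_1 on
standardized features with the 0/1 label as a numeric response; lambda is
chosen on a geometric grid by internal cross-validation, and the selected
features are exactly those with nonzero coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.linear_model import Lasso, LassoCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "mutual_information",
    "quantile_discretize",
    "default_k",
    "MRMRSelector",
    "LassoSelector",
    "MrmrConfig",
    "LassoFit",
    "mrmr_rank",
    "lasso_select",
]

_LOG_BASES = {"natural": math.e, "2": 2.0, 2: 2.0}


def mutual_information(joint_counts: np.ndarray, log_base: str | int = "natural") -> float:
    """Mutual information of two discrete variables from their joint counts.

    Computes sum_{x,y} p(x,y) * log(p(x,y) / (p(x) p(y))) with the usual
    convention 0 * log(0/..) = 0.  Symmetric and nonnegative.

    Parameters
    ----------
    joint_counts
        Nonnegative integer (or real) contingency matrix; rows and columns
        are the two variables' values.
    log_base
        ``"natural"`` (nats, default) or ``"2"`` (bits).
    """
    counts = np.asarray(joint_counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("joint_counts must be a 2-D contingency matrix")
    if (counts < 0).any():
        raise ValueError("joint_counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("joint_counts must contain at least one observation")
    p = counts / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (px * py), 1.0)
        terms = np.where(p > 0, p * np.log(ratio), 0.0)
    mi = float(terms.sum()) / math.log(_LOG_BASES[log_base])
    return max(mi, 0.0)  # clip away -0.0 / rounding noise


def quantile_discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin a continuous vector into ``n_bins`` quantile bins (integer codes)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def default_k(n_features: int) -> int:
    """Number of features the mRMR stage selects: ceil(log2(p)), at least 1.

    For a 7289-feature panel this gives 13.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return max(1, math.ceil(math.log2(n_features)))


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    counts = np.zeros((len(ua), len(ub)))
    np.add.at(counts, (ia, ib), 1)
    return counts


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy forward minimum-redundancy-maximum-relevance selection.

    Parameters
    ----------
    k : int or "auto"
        Number of features to select; ``"auto"`` uses the ceil(log2(p))
        heuristic.
    relevance : {"f-statistic", "discrete-mi"}
        Relevance estimator between each feature and the class.
    redundancy : {"absolute-pearson", "discrete-mi"}
        Redundancy estimator between feature pairs.
    n_bins : int
        Quantile bins for the discrete-mi estimators; features whose
        values are already small integers are used as-is.
    log_base : {"natural", "2"}
        Logarithm base for mutual information.

    Attributes
    ----------
    ranking_ : list of int
        Selected column indices, in greedy order.
    scores_ : list of float
        Criterion value of each pick at the step it was made.
    support_ : ndarray of bool
        Mask of selected features.
    """

    def __init__(self, k="auto", relevance="f-statistic",
                 redundancy="absolute-pearson", n_bins=10, log_base="natural"):
        self.k = k
        self.relevance = relevance
        self.redundancy = redundancy
        self.n_bins = n_bins
        self.log_base = log_base

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        n, p = X.shape
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        k = default_k(p) if self.k == "auto" else int(self.k)
        if not 1 <= k <= p:
            raise ValueError(f"k={k} out of range [1, {p}]")

        if self.relevance == "discrete-mi" or self.redundancy == "discrete-mi":
            binned = np.empty_like(X, dtype=int)
            for j in range(p):
                col = X[:, j]
                if np.allclose(col, np.round(col)) and np.ptp(col) < self.n_bins:
                    binned[:, j] = col.astype(int)
                else:
                    binned[:, j] = quantile_discretize(col, self.n_bins)

        if self.relevance == "f-statistic":
            with np.errstate(divide="ignore", invalid="ignore"):
                rel, _ = f_classif(X, y)
            rel = np.nan_to_num(rel, nan=0.0, posinf=0.0)  # constant cols -> 0
        elif self.relevance == "discrete-mi":
            rel = np.array([
                mutual_information(_contingency(binned[:, j], y), self.log_base)
                for j in range(p)
            ])
        else:
            raise ValueError(f"unknown relevance estimator {self.relevance!r}")

        if self.redundancy == "absolute-pearson":
            sd = X.std(axis=0)
            Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

            def red_col(j):  # |corr| against column j, constants -> 0
                r = np.abs(Z.T @ Z[:, j]) / n
                r[sd == 0] = 0.0
                return r if sd[j] > 0 else np.zeros(p)
        elif self.redundancy == "discrete-mi":
            def red_col(j):
                return np.array([
                    mutual_information(_contingency(binned[:, i], binned[:, j]),
                                       self.log_base)
                    for i in range(p)
                ])
        else:
            raise ValueError(f"unknown redundancy estimator {self.redundancy!r}")

        selected: list[int] = []
        scores: list[float] = []
        red_sum = np.zeros(p)
        remaining = np.ones(p, dtype=bool)
        for step in range(k):
            crit = rel - (red_sum / step if step else 0.0)
            crit = np.where(remaining, crit, -np.inf)
            j = int(np.argmax(crit))  # first max: lowest index wins ties
            selected.append(j)
            scores.append(float(crit[j]))
            remaining[j] = False
            if step < k - 1:
                red_sum += red_col(j)

        self.ranking_ = selected
        self.scores_ = scores
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


class LassoSelector(SelectorMixin, BaseEstimator):
    """L1-penalized linear selection with cross-validated penalty.

    Features are standardized to zero mean / unit variance on the fitting
    data; the binary label is treated as a numeric 0/1 response.  The
    penalty is chosen from a geometric grid of ``n_alphas`` points spanning
    [alpha_max, eps * alpha_max] by ``cv_folds``-fold cross-validation on
    squared error, unless a fixed ``alpha`` is supplied.  Selected features
    are exactly those whose coefficient the coordinate-descent solver
    leaves nonzero.

    A logistic variant (L1-penalized logistic regression with C chosen by
    stratified CV) is available via ``logistic=True``.
    """

    def __init__(self, cv_folds=10, seed=0, alpha=None, n_alphas=100,
                 eps=1e-3, logistic=False):
        self.cv_folds = cv_folds
        self.seed = seed
        self.alpha = alpha
        self.n_alphas = n_alphas
        self.eps = eps
        self.logistic = logistic

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        scaler = StandardScaler()
        Z = scaler.fit_transform(X)
        if self.logistic:
            cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.seed)
            model = LogisticRegressionCV(
                l1_ratios=[1.0], solver="liblinear", cv=cv, Cs=self.n_alphas,
                scoring="accuracy", random_state=self.seed,
            ).fit(Z, y.astype(int))
            coef = model.coef_.ravel()
            self.alpha_ = float(1.0 / model.C_[0])
            self.alpha_grid_ = (1.0 / np.asarray(model.Cs_)).tolist()
        elif self.alpha is not None:
            model = Lasso(alpha=self.alpha).fit(Z, y)
            coef = model.coef_
            self.alpha_ = float(self.alpha)
            self.alpha_grid_ = [float(self.alpha)]
        else:
            if X.shape[0] < self.cv_folds:
                raise ValueError(
                    f"need at least cv_folds={self.cv_folds} samples, "
                    f"got {X.shape[0]}"
                )
            cv = KFold(self.cv_folds, shuffle=True, random_state=self.seed)
            model = LassoCV(alphas=self.n_alphas, eps=self.eps, cv=cv).fit(Z, y)
            coef = model.coef_
            self.alpha_ = float(model.alpha_)
            self.alpha_grid_ = np.sort(model.alphas_)[::-1].tolist()
        self.coef_ = np.asarray(coef, dtype=float)
        self.support_ = self.coef_ != 0.0
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimators, operating on FeatureTable.

@dataclass
class MrmrConfig:
    k: int | str = "auto"
    relevance_estimator: str = "f-statistic"
    redundancy_estimator: str = "absolute-pearson"
    n_bins: int = 10
    log_base: str = "natural"


@dataclass
class LassoFit:
    coefficients: np.ndarray
    penalty: float
    alpha_grid: list[float] = field(repr=False)
    cv_folds: int
    selected_mask: np.ndarray
    selected_features: list[str]


def mrmr_rank(table, config: MrmrConfig | None = None) -> list[tuple[str, float]]:
    """Greedy mRMR ranking of a FeatureTable; returns (name, score) pairs."""
    config = config or MrmrConfig()
    sel = MRMRSelector(
        k=config.k, relevance=config.relevance_estimator,
        redundancy=config.redundancy_estimator, n_bins=config.n_bins,
        log_base=config.log_base,
    ).fit(table.values, table.labels)
    return [(table.feature_names[j], s) for j, s in zip(sel.ranking_, sel.scores_)]


def lasso_select(table, cv_folds: int = 10, seed: int = 0,
                 logistic: bool = False) -> LassoFit:
    """Cross-validated LASSO selection on a FeatureTable."""
    sel = LassoSelector(cv_folds=cv_folds, seed=seed, logistic=logistic)
    sel.fit(table.values, table.labels)
    names = [f for f, m in zip(table.feature_names, sel.support_) if m]
    return LassoFit(
        coefficients=sel.coef_, penalty=sel.alpha_, alpha_grid=sel.alpha_grid_,
        cv_folds=cv_folds, selected_mask=sel.support_, selected_features=names,
    )
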