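import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import hadamard

from radwise.io import FeatureTable
from radwise.selectors import (LassoSelector, MRMRSelector, MrmrConfig,
                               default_k, lasso_select, mrmr_rank,
                               mutual_information, quantile_discretize)


def mi_brute(counts, base=math.e):
    """Independent oracle: direct cell-by-cell summation."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            pxy = counts[i, j] / total
            if pxy == 0:
                continue
            px = counts[i, :].sum() / total
            py = counts[:, j].sum() / total
            mi += pxy * math.log(pxy / (px * py), base)
    return mi


class TestMutualInformation:
    def test_empirical_independence_is_zero(self):
        assert mutual_information([[1, 1], [1, 1]]) == pytest.approx(0.0)

    def test_identical_balanced_binary_gives_one_bit(self):
        assert mutual_information([[2, 0], [0, 2]], log_base="2") == pytest.approx(1.0)

    def test_matches_brute_force_cell_sum(self):
        counts = [[2, 1], [1, 2]]
        assert mutual_information(counts) == pytest.approx(mi_brute(counts))

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([[0, 0], [0, 0]])

    @given(st.lists(st.integers(0, 6), min_size=6, max_size=6))
    @settings(deadline=None)
    def test_symmetry_and_nonnegativity(self, cells):
        m = np.array(cells).reshape(2, 3)
        if m.sum() == 0:
            return
        mi = mutual_information(m)
        assert mi >= 0
        assert mi == pytest.approx(mutual_information(m.T))


class TestQuantileDiscretize:
    def test_balanced_bins_on_uniform_data(self):
        x = np.arange(100, dtype=float)
        codes = quantile_discretize(x, 4)
        assert set(codes) == {0, 1, 2, 3}
        assert np.bincount(codes).max() - np.bincount(codes).min() <= 1


class TestDefaultK:
    @pytest.mark.parametrize("p,expected", [(7289, 13), (2, 1), (1024, 10),
                                            (1, 1), (1025, 11)])
    def test_log2_ceiling(self, p, expected):
        assert default_k(p) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            default_k(0)


def mrmr_exhaustive_oracle(X, y, k, n_bins=10):
    """Stepwise exhaustive maximization of relevance - mean redundancy.

    Independent of the greedy implementation: at each step, every
    remaining feature's criterion is recomputed from scratch with the
    brute-force MI oracle.
    """

    def joint(a, b):
        ua, ub = np.unique(a), np.unique(b)
        m = np.zeros((len(ua), len(ub)))
        for x_, y_ in zip(a, b):
            m[np.where(ua == x_)[0][0], np.where(ub == y_)[0][0]] += 1
        return m

    p = X.shape[1]
    selected = []
    for _ in range(k):
        best, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            score = mi_brute(joint(y, X[:, j]))
            if selected:
                score -= np.mean([mi_brute(joint(X[:, s], X[:, j]))
                                  for s in selected])
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
    return selected


class TestMRMRSelector:
    def _discrete_panel(self, seed=0, n=40, p=5):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        y = ((X[:, 0] + X[:, 2] + rng.integers(0, 2, n)) > 2).astype(int)
        if len(np.unique(y)) < 2:  # pragma: no cover
            y[0] = 1 - y[0]
        return X, y

    def test_k1_maximizes_relevance_alone(self):
        X, y = self._discrete_panel()
        sel = MRMRSelector(k=1, relevance="discrete-mi",
                           redundancy="discrete-mi").fit(X, y)
        rels = [mutual_information(np.histogram2d(
            y, X[:, j], bins=[2, 3])[0]) for j in range(X.shape[1])]
        assert sel.ranking_[0] == int(np.argmax(rels))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_matches_exhaustive_oracle(self, seed):
        X, y = self._discrete_panel(seed=seed, p=6)
        sel = MRMRSelector(k=3, relevance="discrete-mi",
                           redundancy="discrete-mi").fit(X, y)
        assert sel.ranking_ == mrmr_exhaustive_oracle(X, y, 3)

    def test_exact_copy_penalized_below_weaker_independent_feature(self):
        # B duplicates A; C is weaker but independent: after A is picked,
        # B's criterion drops by I(A,B)=H(A) and C outranks it.
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        a = np.where(rng.random(200) < 0.9, y, 1 - y).astype(float)
        c = np.where(rng.random(200) < 0.8, y, 1 - y).astype(float)
        X = np.column_stack([a, a.copy(), c])
        sel = MRMRSelector(k=2, relevance="discrete-mi",
                           redundancy="discrete-mi").fit(X, y)
        assert sel.ranking_[0] == 0
        assert sel.ranking_[1] == 2

    def test_constant_feature_never_beats_informative(self):
        X, y = self._discrete_panel()
        X = np.column_stack([np.full(len(y), 3.0), X])
        sel = MRMRSelector(k=2).fit(X, y)  # f-statistic mode
        assert 0 not in sel.ranking_

    def test_output_length_and_uniqueness(self, small_panel):
        table, _ = small_panel
        sel = MRMRSelector(k=9).fit(table.values, table.labels)
        assert len(sel.ranking_) == 9
        assert len(set(sel.ranking_)) == 9

    def test_auto_k_uses_log2_heuristic(self, small_panel):
        table, _ = small_panel
        sel = MRMRSelector().fit(table.values, table.labels)
        assert len(sel.ranking_) == default_k(table.n_features)

    def test_k_above_p_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="out of range"):
            MRMRSelector(k=4).fit(tiny_table.values, tiny_table.labels)

    def test_mrmr_rank_wrapper_returns_names(self, small_panel):
        table, _ = small_panel
        ranked = mrmr_rank(table, MrmrConfig(k=3))
        assert len(ranked) == 3
        assert all(name in table.feature_names for name, _ in ranked)

    def test_deterministic(self, small_panel):
        table, _ = small_panel
        r1 = MRMRSelector(k=5).fit(table.values, table.labels).ranking_
        r2 = MRMRSelector(k=5).fit(table.values, table.labels).ranking_
        assert r1 == r2


class TestLassoSelector:
    def _orthonormal_design(self):
        H = hadamard(8).astype(float)
        return H[:, 1:]  # zero-mean, unit-variance, mutually orthogonal

    def test_alpha_at_max_gives_empty_selection(self):
        X = self._orthonormal_design()
        rng = np.random.default_rng(0)
        y = X @ np.array([0.8, 0, 0.4, 0, 0, 0, 0]) + 0.05 * rng.normal(size=8)
        alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / len(y)
        sel = LassoSelector(alpha=alpha_max * 1.001).fit(X, y)
        assert sel.support_.sum() == 0

    @pytest.mark.parametrize("alpha", [0.05, 0.2, 0.5])
    def test_soft_threshold_closed_form_on_orthonormal_design(self, alpha):
        # with X'X = nI the solver must return soft(rho_j, alpha),
        # rho_j = x_j'(y - ybar)/n -- the closed-form orthogonal oracle
        X = self._orthonormal_design()
        rng = np.random.default_rng(1)
        y = X @ np.array([0.9, -0.6, 0.3, 0, 0, 0.1, 0]) + 0.02 * rng.normal(size=8)
        sel = LassoSelector(alpha=alpha).fit(X, y)
        rho = X.T @ (y - y.mean()) / len(y)
        expected = np.sign(rho) * np.maximum(np.abs(rho) - alpha, 0.0)
        np.testing.assert_allclose(sel.coef_, expected, atol=1e-6)

    def test_strong_feature_found_among_noise(self):
        # one feature with per-feature AUC ~0.95 among 200 noise features
        rng = np.random.default_rng(42)
        n = 100
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 201))
        X[:, 77] = y * 2.3 + rng.normal(size=n)  # d ~ 2.3 -> AUC ~ 0.95
        sel = LassoSelector(seed=0).fit(X, y)
        assert sel.support_[77]

    def test_scale_invariance_of_selection(self, small_panel):
        table, _ = small_panel
        sel1 = LassoSelector(seed=0).fit(table.values, table.labels)
        scaled = table.values.copy()
        scaled[:, 4] *= 1000.0
        sel2 = LassoSelector(seed=0).fit(scaled, table.labels)
        np.testing.assert_array_equal(sel1.support_, sel2.support_)

    def test_penalty_from_declared_grid(self, small_panel):
        table, _ = small_panel
        fit = lasso_select(table, cv_folds=5, seed=0)
        assert any(math.isclose(fit.penalty, a, rel_tol=1e-9)
                   for a in fit.alpha_grid)
        assert (fit.coefficients != 0).sum() == len(fit.selected_features)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        with pytest.raises(ValueError, match="both classes"):
            LassoSelector().fit(X, np.zeros(20))

    def test_deterministic(self, small_panel):
        table, _ = small_panel
        s1 = LassoSelector(seed=3).fit(table.values, table.labels)
        s2 = LassoSelector(seed=3).fit(table.values, table.labels)
        np.testing.assert_array_equal(s1.support_, s2.support_)
        assert s1.alpha_ == s2.alpha_

    def test_logistic_variant_selects_signal(self, small_panel):
        table, truth = small_panel
        sel = LassoSelector(cv_folds=5, seed=0, logistic=True).fit(
            table.values, table.labels)
        picked = {f for f, m in zip(table.feature_names, sel.support_) if m}
        assert picked & set(truth.planted)
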