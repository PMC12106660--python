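"""Evaluation protocol: AUC oracle equivalence, fold plans, nested CV,
ensembling, window selection and significance tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorbci.evaluate import (FoldPlan, auc_roc, best_window_select,
                              ensemble_predict, ensemble_weights,
                              make_fold_plan, nested_cv,
                              plain_kfold_with_selection, roc_curve,
                              ttest_one_sample, ttest_paired)
from odorbci.preprocess import Window


def auc_bruteforce(scores, labels):
    """Independent oracle: enumerate all (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking(self):
        assert auc_roc(np.array([0.1, 0.2, 0.8, 0.9]),
                       np.array([0, 0, 1, 1])) == 1.0

    def test_worked_example(self):
        """Hand case: scores [0.1, 0.4, 0.35, 0.8], labels [0,0,1,1] ->
        3 of 4 positive-negative pairs correctly ordered."""
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert auc_roc(scores, labels) == pytest.approx(0.75)
        assert auc_bruteforce(scores, labels) == pytest.approx(0.75)

    def test_oracle_equivalence_small_n(self):
        """Rank-statistic AUC equals pairwise enumeration exactly for all
        random instances with n <= 12, including ties."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 13)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = 1
            if labels.all() or not labels.any():
                continue
            scores = rng.integers(0, 5, n).astype(float)  # ties likely
            assert auc_roc(scores, labels) == pytest.approx(
                auc_bruteforce(scores, labels), abs=1e-12)

    def test_random_scores_average_half(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.zeros(20), np.ones(60)].astype(int)
        aucs = [auc_roc(rng.random(80), labels) for _ in range(2000)]
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc_roc(np.array([0.1, 0.2]), np.array([1, 1]))

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=30), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_negation_symmetry(self, scores, data):
        scores = np.asarray(scores)
        labels = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=len(scores), max_size=len(scores))))
        if labels.sum() in (0, len(labels)):
            labels[0], labels[-1] = 0, 1
        assert auc_roc(scores, labels) + auc_roc(-scores, labels) \
            == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(40)
        labels = (rng.random(40) > 0.4).astype(int)
        a = auc_roc(scores, labels)
        assert auc_roc(np.exp(scores), labels) == pytest.approx(a)
        assert auc_roc(3 * scores + 7, labels) == pytest.approx(a)

    def test_matches_trapezoidal_curve_area(self, rng):
        scores = rng.random(60)
        labels = (rng.random(60) > 0.5).astype(int)
        curve = roc_curve(scores, labels)
        area = np.trapezoid(curve.tpr, curve.fpr)
        assert area == pytest.approx(auc_roc(scores, labels))


class TestFoldPlan:
    def test_stratification_arithmetic(self):
        """80 trials at 60/20: every outer test fold holds 8 trials, 6/2."""
        labels = np.r_[np.ones(60), np.zeros(20)].astype(int)
        plan = make_fold_plan(labels, 10, 10, seed=0)
        for _, te in plan.outer:
            assert len(te) == 8
            assert labels[te].sum() == 6

    def test_partition_and_disjoint(self):
        labels = np.r_[np.ones(60), np.zeros(20)].astype(int)
        plan = make_fold_plan(labels, 10, 10, seed=3)
        plan.validate(80)  # raises on any violation

    def test_same_seed_identical(self):
        labels = np.r_[np.ones(30), np.zeros(30)].astype(int)
        a = make_fold_plan(labels, 5, 5, seed=9)
        b = make_fold_plan(labels, 5, 5, seed=9)
        for (ta, sa), (tb, sb) in zip(a.outer, b.outer):
            assert np.array_equal(ta, tb) and np.array_equal(sa, sb)

    def test_too_few_trials_errors(self):
        labels = np.r_[np.ones(5), np.zeros(30)].astype(int)
        with pytest.raises(ValueError):
            make_fold_plan(labels, 10, 10)


class TestEnsemble:
    def test_identical_members_equal_single(self, rng):
        class Fixed:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack([1 - self.p, self.p])

        p = rng.random(6)
        members = [Fixed(p) for _ in range(5)]
        out = ensemble_predict(members, np.array([0.6, 0.7, 0.8, 0.55, 0.9]),
                               np.zeros((6, 1)))
        assert np.allclose(out, p)

    def test_degenerate_weight_selects_member(self):
        w = ensemble_weights(np.array([0.9, 0.5, 0.5]))
        assert w[0] == pytest.approx(1.0, abs=1e-4)
        assert w.sum() == pytest.approx(1.0)

    def test_weights_sum_to_one(self, rng):
        for _ in range(10):
            w = ensemble_weights(rng.random(7))
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0)


class TestBestWindow:
    W = [Window(0.0, 0.25), Window(0.15, 0.40), Window(0.30, 0.55)]

    def test_single_window(self):
        w, test_auc = best_window_select({self.W[0]: (0.6, 0.55)})
        assert w == self.W[0] and test_auc == 0.55

    def test_max_validation_selected(self):
        res = {self.W[0]: (0.52, 0.5), self.W[1]: (0.6, 0.58),
               self.W[2]: (0.71, 0.64)}
        w, test_auc = best_window_select(res)
        assert w == self.W[2] and test_auc == 0.64

    def test_tie_breaks_to_earliest(self):
        res = {self.W[2]: (0.7, 0.61), self.W[0]: (0.7, 0.52)}
        w, test_auc = best_window_select(res)
        assert w == self.W[0] and test_auc == 0.52


class TestTTests:
    def test_all_at_chance(self):
        r = ttest_one_sample(np.array([0.5, 0.5, 0.5001, 0.4999]), 0.5)
        assert r.t == pytest.approx(0.0, abs=0.01)
        assert r.p == pytest.approx(0.5, abs=0.01)

    def test_df_convention(self, rng):
        r = ttest_one_sample(0.5 + 0.05 * rng.standard_normal(52), 0.5)
        assert r.df == 51

    def test_hand_computed_t(self):
        r = ttest_one_sample(np.array([0.6, 0.7, 0.8]), 0.5)
        assert r.t == pytest.approx(3.464, abs=1e-3)

    def test_paired_swap_negates_t(self, rng):
        a = rng.random(15)
        b = rng.random(15)
        r1 = ttest_paired(a, b)
        r2 = ttest_paired(b, a)
        assert r2.t == pytest.approx(-r1.t)
        assert r2.p == pytest.approx(r1.p)

    def test_identical_pairs(self):
        a = np.array([0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            ttest_paired(a, a)

    def test_p_decreases_with_n(self, rng):
        base = 0.1 + 0.05 * rng.standard_normal(64)
        small = ttest_one_sample(0.5 + base[:8], 0.5)
        large = ttest_one_sample(0.5 + base, 0.5)
        assert large.p < small.p


class TestNestedCv:
    @staticmethod
    def _factory(C=1.0):
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(C=C, max_iter=1000)

    def test_models_per_outer_fold(self, rng):
        """Each outer fold trains an ensemble of k_inner models, weighted by
        their validation AUC."""
        X = rng.standard_normal((40, 5))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        plan = make_fold_plan(y, 5, 10, seed=0)
        res = nested_cv(X, y, self._factory, plan)
        assert len(res.fold_aucs) == 5
        for w in res.weights:
            assert len(w) == 10
            assert w.sum() == pytest.approx(1.0)

    def test_strong_effect_high_auc(self, rng):
        X = rng.standard_normal((60, 4))
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X[y == 1, 0] += 4.0
        plan = make_fold_plan(y, 5, 5, seed=1)
        res = nested_cv(X, y, self._factory, plan,
                        param_grid=[0.1, 1.0, 10.0])
        assert res.mean_auc > 0.9
        assert all(p in (0.1, 1.0, 10.0) for p in res.selected)

    def test_leakage_audit_rejects_bad_plan(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        plan = make_fold_plan(y, 5, 5, seed=0)
        # corrupt: put an outer-test trial into an inner training split
        bad = plan.inner[0][0][0].copy()
        bad[0] = plan.outer[0][1][0]
        plan.inner[0][0] = (bad, plan.inner[0][0][1])
        with pytest.raises(AssertionError):
            nested_cv(X, y, self._factory, plan)


def test_plain_kfold_selection_is_optimistic_on_null(rng):
    """On label-independent data, selecting the best hyperparameter on the
    same folds that are reported inflates the AUC above the nested-CV
    estimate (sign test over seeds)."""
    from scipy import stats

    from odorbci.linear import L1LogRegFactory

    grid = [0.05, 0.5, 5.0]
    factory = L1LogRegFactory()
    wins = 0
    n_seeds = 12
    for seed in range(n_seeds):
        r = np.random.default_rng(seed)
        X = r.standard_normal((40, 20))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        r.shuffle(y)
        plain = plain_kfold_with_selection(X, y, factory.make, grid, k=5,
                                           seed=seed)
        plan = make_fold_plan(y, 5, 5, seed=seed)
        nested = nested_cv(X, y, factory.make, plan, param_grid=grid).mean_auc
        wins += plain > nested
    assert stats.binomtest(wins, n_seeds, 0.5, "greater").pvalue < 0.05
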