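"""Stepwise logistic selection, SCG network, repeated splits, ROC AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from vfnet.classify import (
    ForwardStepwiseLogistic,
    RepeatedSplitResult,
    ScgMlpClassifier,
    StepwiseNN,
    evaluate_repeated_split,
    roc_auc,
)


def informative_dataset(rng, n=60, shift=3.0, n_noise=9):
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    X = rng.standard_normal((n, n_noise + 1))
    X[:, 0] += shift * y  # only the first column is informative
    cols = ["signal"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestRocAuc:
    def test_perfect_and_reversed_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_ties_contribute_half(self):
        assert roc_auc([0.5, 0.5], [0, 1]) == 0.5

    def test_equals_mann_whitney_u(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = rng.normal(0, 1, 30) + 0.5 * y
            u = sstats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
            assert roc_auc(s, y) == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(0, 1, 40)
        assert roc_auc(s, y) == roc_auc(np.exp(3 * s) + 7, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestForwardStepwise:
    def test_informative_feature_selected_first(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            X, y = informative_dataset(rng)
            fit = ForwardStepwiseLogistic().fit(X, y)
            hits += bool(fit.selected_features_) and fit.selected_features_[0] == "signal"
        assert hits >= 19

    def test_null_selection_rate_consistent_with_multiplicity(self):
        """With 10 pure-noise candidates, some datasets select a feature by
        chance; the per-dataset rate stays near 1 - (1 - alpha)^10."""
        selected = 0
        n_rep = 120
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            X = pd.DataFrame(rng.standard_normal((60, 10)))
            y = np.r_[np.zeros(30, int), np.ones(30, int)]
            fit = ForwardStepwiseLogistic().fit(X, y)
            selected += bool(fit.selected_features_)
        rate = selected / n_rep
        expected = 1 - 0.95**10  # ~0.40
        assert abs(rate - expected) < 0.15

    def test_deterministic_selection_path(self, rng):
        X, y = informative_dataset(rng)
        a = ForwardStepwiseLogistic().fit(X, y)
        b = ForwardStepwiseLogistic().fit(X, y)
        assert a.selected_features_ == b.selected_features_
        np.testing.assert_array_equal(a.coef_, b.coef_)

    def test_entry_pvalues_below_threshold(self, rng):
        X, y = informative_dataset(rng)
        fit = ForwardStepwiseLogistic(p_enter=0.05).fit(X, y)
        assert all(s.p < 0.05 for s in fit.steps_)

    def test_separation_flagged(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        fit = ForwardStepwiseLogistic().fit(X, y)
        assert fit.separated_
        assert np.isfinite(fit.coef_).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ForwardStepwiseLogistic().fit(pd.DataFrame(rng.normal(size=(8, 2))),
                                          np.ones(8, int))

    def test_score_test_agrees_with_lr_on_strong_signal(self, rng):
        X, y = informative_dataset(rng)
        lr = ForwardStepwiseLogistic(test="lr").fit(X, y)
        sc = ForwardStepwiseLogistic(test="score").fit(X, y)
        assert lr.selected_features_[0] == sc.selected_features_[0] == "signal"

    def test_sklearn_logistic_cross_check(self, rng):
        """Full-model coefficients match sklearn's unpenalised logistic fit."""
        from sklearn.linear_model import LogisticRegression

        X, y = informative_dataset(rng, n_noise=1)
        fit = ForwardStepwiseLogistic(p_enter=1.1, max_steps=2, standardize=False).fit(X, y)
        sk = LogisticRegression(C=np.inf, max_iter=500).fit(
            X[fit.selected_features_], y
        )
        order = [fit.selected_features_.index(c) for c in fit.selected_features_]
        np.testing.assert_allclose(
            np.sort(fit.coef_), np.sort(sk.coef_[0]), rtol=1e-3, atol=1e-3
        )


class TestScgNetwork:
    def test_linearly_separable_reaches_full_training_accuracy(self, rng):
        X = pd.DataFrame({"a": np.r_[rng.normal(-3, 0.3, 25), rng.normal(3, 0.3, 25)],
                          "b": rng.normal(0, 1, 50)})
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        net = ScgMlpClassifier(random_state=0).fit(X, y)
        assert (net.predict(X) == y).mean() == 1.0

    def test_zero_offset_warns_about_symmetry(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.warns(RuntimeWarning, match="symmetry"):
            ScgMlpClassifier(init_offset=0.0, max_iter=5, random_state=0).fit(X, y)

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        a = ScgMlpClassifier(random_state=7).fit(X, y).predict_proba(X)
        b = ScgMlpClassifier(random_state=7).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_probabilities_sum_to_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        P = ScgMlpClassifier(random_state=1).fit(X, y).predict_proba(X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestRepeatedSplit:
    def test_perfectly_separated_always_auc_one(self, rng):
        X = pd.DataFrame({"x": np.r_[np.full(20, -5.0), np.full(20, 5.0)]
                          + rng.normal(0, 0.1, 40)})
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = evaluate_repeated_split(X, y, ForwardStepwiseLogistic(p_enter=1.1,
                                                                    max_steps=1),
                                      repetitions=20, master_seed=0)
        assert (res.aucs == 1.0).all()

    def test_null_features_auc_near_half(self, rng):
        X = pd.DataFrame(rng.standard_normal((58, 5)))
        y = np.r_[np.zeros(30, int), np.ones(28, int)]
        res = evaluate_repeated_split(
            X, y, ForwardStepwiseLogistic(p_enter=1.1, max_steps=1),
            repetitions=100, master_seed=3,
        )
        assert abs(res.mean_auc - 0.5) < 0.08

    def test_single_repetition_interval_collapses(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        res = evaluate_repeated_split(X, y, ForwardStepwiseLogistic(p_enter=1.1,
                                                                    max_steps=1),
                                      repetitions=1, master_seed=0)
        assert res.ci95 == (res.aucs[0], res.aucs[0])

    def test_splits_are_stratified_and_70_30(self, rng):
        """Instrumented estimator: fit must see only the training rows and
        both classes; scoring happens on the complement."""
        seen = []

        class Probe(ForwardStepwiseLogistic):
            def fit(self, X, y):
                seen.append((np.asarray(X).shape[0], np.bincount(np.asarray(y))))
                return super().fit(X, y)

        X = pd.DataFrame(rng.standard_normal((40, 3)))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        evaluate_repeated_split(X, y, Probe(p_enter=1.1, max_steps=1),
                                repetitions=5, master_seed=0)
        for n_rows, counts in seen:
            assert n_rows == 28  # 70% of 40
            assert counts.tolist() == [14, 14]

    def test_no_test_leakage_into_selection(self, rng):
        """The informative column's test rows are never visible at fit time."""
        captured = []

        class Probe(StepwiseNN):
            def fit(self, X, y):
                captured.append(np.asarray(X)[:, 0].copy())
                return super().fit(X, y)

        X, y = informative_dataset(rng, n=30, n_noise=2)
        all_vals = X["signal"].to_numpy()
        res = evaluate_repeated_split(X, y, Probe(), repetitions=3, master_seed=1)
        for train_vals in captured:
            assert len(train_vals) < len(all_vals)
        assert isinstance(res, RepeatedSplitResult)


def test_stepwise_nn_falls_back_to_best_feature_on_null(rng):
    X = pd.DataFrame(rng.standard_normal((30, 4)))
    y = np.r_[np.zeros(15, int), np.ones(15, int)]
    model = StepwiseNN(random_state=0).fit(X, y)
    assert model.fallback_
    assert model.predict_proba(X).shape == (30, 2)
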