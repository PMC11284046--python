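"""Boosted-tree classifier configuration, losses, and metrics."""

import math
import warnings

import numpy as np
import pytest

from caemgbdt.gbdt import (
    GBDTConfig,
    GBDTSubtypeClassifier,
    evaluate,
    fit_gbdt,
    logloss,
    predict,
)


def _blobs(n_per_class=25, k=2, d=6, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([
        rng.normal(size=(n_per_class, d)) + sep * rng.normal(size=d)
        for _ in range(k)
    ])
    y = np.repeat(np.arange(k), n_per_class)
    return X, y


class TestLogloss:
    def test_perfect_prediction_near_zero(self):
        assert logloss([1.0], [1.0 - 1e-12]) < 1e-9

    def test_coin_flip_is_ln2(self):
        assert logloss([1.0, 0.0], [0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_quarter_probability(self):
        assert logloss([1.0], [0.25]) == pytest.approx(1.386294, abs=1e-6)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=50).astype(float)
        p = rng.uniform(0.01, 0.99, size=50)
        brute = -sum(
            yi * math.log(pi) + (1 - yi) * math.log(1 - pi) for yi, pi in zip(y, p)
        ) / 50
        assert abs(logloss(y, p) - brute) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            logloss([1.0], [0.5, 0.5])


class TestConfig:
    def test_defaults_match_method_settings(self):
        cfg = GBDTConfig()
        assert (cfg.learning_rate, cfg.n_estimators, cfg.max_depth) == (0.1, 300, 3)
        assert (cfg.min_samples_leaf, cfg.min_samples_split, cfg.subsample) == (5, 5, 0.8)

    @pytest.mark.parametrize("kwargs", [
        {"n_estimators": 301}, {"learning_rate": 0.0}, {"subsample": 1.5},
        {"loss": "exponential"},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GBDTConfig(**kwargs)


class TestFit:
    def test_separable_training_accuracy_is_one(self):
        X, y = _blobs(n_per_class=50, k=2, sep=8.0)
        clf = fit_gbdt(X, y, GBDTConfig(n_estimators=50))
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_one_vs_all_tree_count_k4(self):
        X, y = _blobs(n_per_class=20, k=4, sep=8.0, seed=2)
        clf = GBDTSubtypeClassifier(n_estimators=300).fit(X, y)
        assert clf.total_trees_ == 1200  # M * K without early stopping

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            GBDTSubtypeClassifier().fit(np.zeros((10, 3)), np.zeros(10))

    def test_small_class_warns(self):
        X, y = _blobs(n_per_class=30, k=2, seed=3)
        X = np.concatenate([X, np.ones((2, X.shape[1]))])
        y = np.concatenate([y, [2, 2]])
        with pytest.warns(UserWarning, match="min_samples_leaf"):
            GBDTSubtypeClassifier(n_estimators=10).fit(X, y)

    def test_staged_training_loss_nonincreasing(self):
        X, y = _blobs(n_per_class=40, k=3, sep=6.0, seed=4)
        clf = GBDTSubtypeClassifier(n_estimators=120, random_state=0).fit(X, y)
        losses = np.array(clf.staged_train_loss_)
        assert np.all(np.diff(losses) <= 1e-9)

    def test_tree_contract_depth_and_leaves(self):
        X, y = _blobs(n_per_class=40, k=2, seed=5)
        clf = GBDTSubtypeClassifier(n_estimators=30).fit(X, y)
        for stage in clf.model_.estimators_:
            for tree in stage:
                assert tree.get_depth() <= 3
                leaf_sizes = tree.tree_.n_node_samples[
                    tree.tree_.children_left == -1]
                assert leaf_sizes.min() >= 5 * 0.8 - 1  # subsampled counts

    def test_shrinkage_limit_approaches_prior(self):
        X, y = _blobs(n_per_class=30, k=2, sep=4.0, seed=6)
        clf = GBDTSubtypeClassifier(n_estimators=20, learning_rate=1e-6).fit(X, y)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba, 0.5, atol=1e-3)

    def test_early_stopping_can_shorten(self):
        X, y = _blobs(n_per_class=60, k=2, sep=10.0, seed=7)
        clf = GBDTSubtypeClassifier(n_estimators=300, early_stopping=True,
                                    random_state=0).fit(X, y)
        assert clf.n_stages_ <= 300


class TestPredict:
    def test_probability_rows_sum_to_one(self):
        X, y = _blobs(n_per_class=25, k=3, seed=8)
        clf = GBDTSubtypeClassifier(n_estimators=30).fit(X, y)
        labels, proba = predict(clf, X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(labels, proba.argmax(axis=1))

    def test_feature_width_mismatch(self):
        X, y = _blobs()
        clf = GBDTSubtypeClassifier(n_estimators=5).fit(X, y)
        with pytest.raises(ValueError, match="layout mismatch"):
            clf.predict(X[:, :-1])


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate(np.array([0, 1, 2, 0]), np.array([0, 1, 2, 0]))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (100.0, 100.0, 100.0, 100.0)

    def test_hand_computed_confusion(self):
        rep = evaluate(np.array([0, 0, 1, 1]), np.array([0, 1, 1, 1]))
        assert rep.accuracy == pytest.approx(75.0)
        assert rep.precision == pytest.approx(83.3, abs=0.05)
        assert rep.recall == pytest.approx(75.0)
        # per-class F1 {2/3, 4/5} -> macro 73.3
        assert rep.f1 == pytest.approx(73.3, abs=0.05)
        np.testing.assert_array_equal(rep.confusion, [[1, 1], [0, 2]])

    def test_confusion_sums_to_n(self):
        rng = np.random.default_rng(9)
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        rep = evaluate(y_true, y_pred, ["a", "b", "c"])
        assert rep.confusion.sum() == 60

    def test_chance_level_balanced_four_class(self):
        rng = np.random.default_rng(10)
        n = 4000
        y_true = rng.integers(0, 4, n)
        y_pred = rng.integers(0, 4, n)
        rep = evaluate(y_true, y_pred)
        assert abs(rep.accuracy - 25.0) < 3.0  # ~4 binomial SDs

    def test_unknown_predicted_class_rejected(self):
        with pytest.raises(ValueError, match="not in class_names"):
            evaluate(np.array([0, 1]), np.array([0, 3]), ["a", "b"])

    def test_report_serialization(self):
        rep = evaluate(np.array([0, 0, 1, 1]), np.array([0, 1, 1, 1]), ["x", "y"])
        d = rep.as_dict()
        assert d["accuracy"] == 75.0
        assert set(d["per_class"]) == {"x", "y"}
        assert "accuracy" in rep.format_table()
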