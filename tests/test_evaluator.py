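"""Metric correctness against brute-force oracles, and the PCA probe audit."""

import numpy as np
import pytest

from harmonytm.evaluator import (binary_metrics, feature_probe_accuracy,
                                 multiclass_weighted_metrics, pca_probe)


def auroc_bruteforce(y, p):
    """Pairwise estimator: fraction of (pos, neg) pairs ranked correctly,
    ties counting one half."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        m = binary_metrics(y, p)
        assert all(m[k] == 1.0 for k in m)

    def test_hand_computed_example(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.4, 0.6, 0.1])
        m = binary_metrics(y, p)
        assert m["accuracy"] == 0.5
        assert m["auroc"] == pytest.approx(0.75)  # 3 of 4 pos-neg pairs won
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 0.5

    def test_constant_prediction_is_chance_auroc(self):
        y = np.array([0, 1, 0, 1, 1])
        p = np.full(5, 0.5)
        assert binary_metrics(y, p)["auroc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(np.ones(4), np.linspace(0.1, 0.9, 4))

    def test_auroc_matches_bruteforce_on_random_instances(self, rng):
        """The implementation agrees exactly (ties = 1/2) with the O(n^2)
        pairwise oracle on a thousand small random instances."""
        for _ in range(1000):
            n = rng.integers(4, 12)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            m = binary_metrics(y, p)
            assert m["auroc"] == pytest.approx(auroc_bruteforce(y, p),
                                               abs=1e-12)


def weighted_oracle(y, yhat, m):
    """Per-class one-vs-rest metrics combined by support weights."""
    n = len(y)
    out = dict(sensitivity=0.0, specificity=0.0, precision=0.0, f1=0.0)
    for k in range(m):
        w = np.sum(y == k) / n
        tp = np.sum((y == k) & (yhat == k))
        fn = np.sum((y == k) & (yhat != k))
        fp = np.sum((y != k) & (yhat == k))
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        out["sensitivity"] += w * sens
        out["specificity"] += w * spec
        out["precision"] += w * prec
        out["f1"] += w * f1
    return out


class TestMulticlassMetrics:
    def test_diagonal_confusion_is_perfect(self):
        y = np.array([0, 1, 2, 2])
        metrics, conf = multiclass_weighted_metrics(y, y, n_classes=3)
        assert metrics["accuracy"] == 1.0
        assert np.array_equal(conf, np.diag([1, 1, 2]))

    def test_three_class_hand_example(self):
        # supports (2, 1, 1); one error: a class-0 sample predicted as 1
        y = np.array([0, 0, 1, 2])
        yhat = np.array([0, 1, 1, 2])
        metrics, conf = multiclass_weighted_metrics(y, yhat, n_classes=3)
        oracle = weighted_oracle(y, yhat, 3)
        for key, val in oracle.items():
            assert metrics[key] == pytest.approx(val, abs=1e-12), key
        assert conf[0, 1] == 1

    def test_majority_prediction_sensitivity_equals_majority_share(self):
        y = np.array([0] * 6 + [1] * 3 + [2])
        yhat = np.zeros(10, dtype=int)
        metrics, _ = multiclass_weighted_metrics(y, yhat, n_classes=3)
        # only class 0 has nonzero recall, weighted by its own share
        assert metrics["sensitivity"] == pytest.approx(0.6 * 1.0)
        assert metrics["accuracy"] == pytest.approx(0.6)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(50):
            m = rng.integers(2, 6)
            n = rng.integers(5, 30)
            y = rng.integers(0, m, size=n)
            yhat = rng.integers(0, m, size=n)
            metrics, conf = multiclass_weighted_metrics(y, yhat, n_classes=m)
            oracle = weighted_oracle(y, yhat, m)
            for key, val in oracle.items():
                assert metrics[key] == pytest.approx(val, abs=1e-12), key
            # marginals conserve the test counts
            assert conf.sum() == n
            assert np.array_equal(conf.sum(axis=1), np.bincount(y, minlength=m))

    def test_label_outside_space_rejected(self):
        with pytest.raises(ValueError):
            multiclass_weighted_metrics(np.array([0, 3]), np.array([0, 1]),
                                        n_classes=3)


class TestPcaProbe:
    def test_separated_clouds_are_read_off_mode_one(self, rng):
        n = 200
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6)) * 0.1
        X[:, 0] += labels * 10.0  # separation >> spread along one axis
        coords, acc = pca_probe(X, labels, labels, seed=0)
        assert acc[("scanner", "mode1")] == 1.0
        assert acc[("disease", "mode1")] == 1.0

    def test_shuffled_labels_probe_at_chance(self, rng):
        n = 400
        X = rng.normal(size=(n, 8))
        labels = rng.permutation(np.repeat([0, 1], n // 2))
        _, acc = pca_probe(X, labels, labels, seed=0)
        assert abs(acc[("disease", "both")] - 0.5) <= 0.1

    def test_scores_centered_and_variance_ordered(self, rng):
        X = rng.normal(size=(100, 5)) * np.array([3, 1, 1, 1, 1])
        coords, _ = pca_probe(X, (X[:, 0] > 0).astype(int),
                              (X[:, 1] > 0).astype(int), seed=0)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-8)
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_constant_columns_are_dropped(self, rng):
        X = rng.normal(size=(50, 4))
        X[:, 2] = 7.0
        labels = (X[:, 0] > 0).astype(int)
        coords, _ = pca_probe(X, labels, labels, seed=0)
        assert coords.shape == (50, 2)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_probe(rng.normal(size=(2, 4)), [0, 1], [0, 1])

    def test_all_constant_features_fall_back_to_majority(self):
        labels = np.array([0] * 20 + [1] * 10)
        coords, acc = pca_probe(np.ones((30, 4)), labels, labels, seed=0)
        assert np.allclose(coords, 0.0)
        assert acc[("disease", "both")] == pytest.approx(2 / 3)

    def test_rank_one_features_fall_back_to_single_mode(self, rng):
        X = np.ones((60, 4))
        X[:, 1] = rng.normal(size=60)
        labels = (X[:, 1] > 0).astype(int)
        coords, acc = pca_probe(X, labels, labels, seed=0)
        assert coords.shape == (60, 2)
        assert np.allclose(coords[:, 1], 0.0)
        assert acc[("disease", "mode1")] == 1.0


def test_feature_probe_requires_two_classes(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(ValueError):
        feature_probe_accuracy(X, np.zeros(10), X, np.zeros(10))
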