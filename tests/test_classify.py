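"""Relief-F ranking and leave-one-out Gaussian-SVM classification."""

import numpy as np
import pandas as pd
import pytest

from phonemark.classify import (
    combine_phonemes,
    confusion_metrics,
    feature_columns,
    loocv_svm,
    relief_f,
)
from phonemark.errors import InsufficientClassError, InvalidArgumentError


def make_table(X, y, phoneme="a", feature_names=None):
    n, d = X.shape
    feature_names = feature_names or [f"f{j}" for j in range(d)]
    df = pd.DataFrame(X, columns=feature_names)
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    df.insert(1, "group", np.where(np.asarray(y) == 1, "pd", "control"))
    df.insert(2, "phoneme", phoneme)
    df.insert(3, "repetition", 0)
    return df


def clusters(n_per_class, d, separation, rng, noise_features=0):
    X0 = rng.standard_normal((n_per_class, d))
    X1 = rng.standard_normal((n_per_class, d)) + separation
    X = np.vstack([X0, X1])
    if noise_features:
        X = np.hstack([X, rng.standard_normal((2 * n_per_class, noise_features))])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestConfusionMetrics:
    def test_reference_confusion(self):
        acc, sens, spec = confusion_metrics(126, 127, 23, 24)
        assert acc == pytest.approx(84.3, abs=0.05)
        assert sens == pytest.approx(84.0, abs=0.05)
        assert spec == pytest.approx(84.7, abs=0.05)

    def test_perfect(self):
        assert confusion_metrics(10, 10, 0, 0) == (100.0, 100.0, 100.0)

    def test_all_negative_predictions(self):
        acc, sens, spec = confusion_metrics(0, 10, 0, 10)
        assert (acc, sens, spec) == (50.0, 0.0, 100.0)

    def test_accuracy_decomposition(self):
        tp, tn, fp, fn = 37, 22, 13, 9
        acc, sens, spec = confusion_metrics(tp, tn, fp, fn)
        p, n = tp + fn, tn + fp
        assert acc == pytest.approx((sens * p + spec * n) / (p + n), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            confusion_metrics(-1, 1, 1, 1)


class TestReliefF:
    def test_separating_feature_ranked_first(self):
        wins = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            sep = np.concatenate([rng.normal(0, 0.3, 50), rng.normal(2, 0.3, 50)])
            noise = rng.standard_normal((100, 4))
            X = np.column_stack([sep, noise])
            y = np.array([0] * 50 + [1] * 50)
            ranked = relief_f(make_table(X, y, feature_names=["sep", "n1", "n2", "n3", "n4"]), k=10)
            wins += ranked[0][0] == "sep"
        assert wins >= 29

    def test_duplicated_feature_equal_weight(self, rng):
        X, y = clusters(20, 1, 2.0, rng)
        X = np.hstack([X, X])  # duplicate the feature
        ranked = dict(relief_f(make_table(X, y, feature_names=["a", "b"]), k=5))
        assert ranked["a"] == pytest.approx(ranked["b"], abs=1e-12)

    def test_constant_feature_zero_weight(self, rng):
        X, y = clusters(20, 1, 2.0, rng)
        X = np.hstack([X, np.ones((len(X), 1))])
        ranked = dict(relief_f(make_table(X, y, feature_names=["a", "const"]), k=5))
        assert ranked["const"] == 0.0

    def test_small_instance_hand_enumeration(self):
        """Literal transcription of the update rule on a tiny instance."""
        X = np.array([[0.0, 0.1], [0.2, 0.9], [1.0, 0.2], [0.8, 1.0],
                      [0.1, 0.5], [0.9, 0.6]])
        y = np.array([0, 0, 1, 1, 0, 1])
        k = 1
        span = X.max(axis=0) - X.min(axis=0)
        Z = (X - X.min(axis=0)) / span
        m = len(X)
        expected = np.zeros(2)
        for i in range(m):
            d2 = np.sum((Z - Z[i]) ** 2, axis=1)
            d2[i] = np.inf
            hit = min((j for j in range(m) if y[j] == y[i] and j != i),
                      key=lambda j: d2[j])
            miss = min((j for j in range(m) if y[j] != y[i]),
                       key=lambda j: d2[j])
            expected += (np.abs(Z[miss] - Z[i]) - np.abs(Z[hit] - Z[i])) / m
        ranked = relief_f(make_table(X, y, feature_names=["a", "b"]), k=k)
        got = dict(ranked)
        assert got["a"] == pytest.approx(expected[0], abs=1e-12)
        assert got["b"] == pytest.approx(expected[1], abs=1e-12)

    def test_insufficient_class_rejected(self, rng):
        X, y = clusters(5, 2, 1.0, rng)
        with pytest.raises(InsufficientClassError):
            relief_f(make_table(X, y), k=10)


class TestLoocvSvm:
    def test_separable_clusters_perfect(self, rng):
        X, y = clusters(20, 2, 10.0, rng)
        report = loocv_svm(make_table(X, y))
        assert report.accuracy == 100.0

    def test_permuted_labels_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = clusters(20, 3, 3.0, rng)
            rng.shuffle(y)  # break the label-feature link
            accs.append(loocv_svm(make_table(X, y)).accuracy)
        assert 35.0 <= np.mean(accs) <= 65.0

    def test_no_leakage_through_scaling(self, rng):
        """A label-copy feature gives 100%; removing it must drop the
        same table to chance — per-fold scaling leaks nothing."""
        n = 20
        X = rng.standard_normal((2 * n, 3))
        y = np.array([0] * n + [1] * n)
        rng.shuffle(y)
        Xleak = np.hstack([X, y[:, None].astype(float)])
        t_leak = make_table(Xleak, y, feature_names=["a", "b", "c", "label"])
        assert loocv_svm(t_leak).accuracy == 100.0
        t_clean = make_table(X, y, feature_names=["a", "b", "c"])
        assert loocv_svm(t_clean).accuracy <= 70.0

    def test_contradictory_duplicate_row(self, rng):
        X, y = clusters(10, 2, 8.0, rng)
        X[10] = X[0]  # same point under both labels
        report = loocv_svm(make_table(X, y))
        assert report.fp + report.fn >= 1

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(InvalidArgumentError):
            loocv_svm(make_table(X, np.zeros(10, dtype=int)))

    def test_deterministic(self, rng):
        X, y = clusters(15, 3, 1.0, rng)
        t = make_table(X, y)
        a = loocv_svm(t)
        b = loocv_svm(t)
        assert a.to_dict() == b.to_dict()


class TestCombinePhonemes:
    def _table(self, phoneme, subjects, rng):
        X = rng.standard_normal((len(subjects), 2))
        # group must be a property of the subject, consistent across phonemes
        y = [int(s[1:]) % 2 for s in subjects]
        df = make_table(X, y, phoneme=phoneme, feature_names=["u", "v"])
        df["subject_id"] = subjects
        return df

    def test_feature_arity(self, rng):
        subs = [f"s{i}" for i in range(8)]
        combined = combine_phonemes([self._table("a", subs, rng),
                                     self._table("e", subs, rng)])
        assert len(feature_columns(combined)) == 4
        assert set(feature_columns(combined)) == {"a_u", "a_v", "e_u", "e_v"}
        assert len(combined) == 8

    def test_missing_subject_dropped(self, rng):
        combined = combine_phonemes([
            self._table("a", [f"s{i}" for i in range(8)], rng),
            self._table("e", [f"s{i}" for i in range(1, 9)], rng),
        ])
        assert len(combined) == 7

    def test_self_combination_keeps_rows(self, rng):
        t = self._table("a", [f"s{i}" for i in range(8)], rng)
        combined = combine_phonemes([t, t])
        assert len(combined) == 8
        assert len(feature_columns(combined)) == 4

    def test_disjoint_subjects_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            combine_phonemes([
                self._table("a", [f"x{i}" for i in range(8)], rng),
                self._table("e", [f"y{i}" for i in range(8)], rng),
            ])
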