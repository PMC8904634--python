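import collections

import numpy as np
import pytest

from celiascan.classify import (
    Dataset,
    accuracy_from_counts,
    apply_standardization,
    dataset_from_table,
    evaluate,
    f1_from_counts,
    fit_classifier,
    fit_fine_knn,
    fit_linear_svm,
    fit_weighted_knn,
    remaining_after_exclusion,
    split_dataset,
    standardize,
    truncate2,
)
from celiascan.features import FrameFeatures, feature_table, summarize_video


def make_dataset(n_per_class: int, rng, spread: float = 0.5, gap: float = 10.0) -> Dataset:
    """Two Gaussian clusters separated by `gap` along the first axis."""
    healthy = rng.normal([0.0, 0.0], spread, size=(n_per_class, 2))
    celiac = rng.normal([gap, 0.0], spread, size=(n_per_class, 2))
    return Dataset(
        vectors=np.vstack([healthy, celiac]),
        labels=np.array(["healthy"] * n_per_class + ["celiac"] * n_per_class),
        ids=np.array([f"v{i}" for i in range(2 * n_per_class)]),
    )


class TestStandardize:
    def test_two_point_column(self):
        scaled, mean, std = standardize(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(scaled, [[-1.0], [1.0]])
        assert mean[0] == 2.0 and std[0] == 1.0

    def test_constant_column_maps_to_zero(self):
        scaled, _, _ = standardize(np.array([[5.0, 1.0], [5.0, 3.0]]))
        np.testing.assert_array_equal(scaled[:, 0], 0.0)

    def test_columns_centered(self, rng):
        scaled, _, _ = standardize(rng.random((20, 4)))
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-12)

    def test_apply_to_held_out(self, rng):
        train = rng.random((10, 3))
        scaled, mean, std = standardize(train)
        np.testing.assert_allclose(apply_standardization(train, mean, std), scaled)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            standardize(np.ones((1, 3)))


class TestSplitDataset:
    def test_exact_stratification(self, rng):
        ds = make_dataset(10, rng)
        train, test = split_dataset(ds, 0.5, seed=7)
        assert len(train) == 10 and len(test) == 10
        for part in (train, test):
            counts = collections.Counter(part.labels)
            assert counts["healthy"] == 5 and counts["celiac"] == 5

    def test_deterministic(self, rng):
        ds = make_dataset(8, rng)
        a = split_dataset(ds, 0.5, seed=3)
        b = split_dataset(ds, 0.5, seed=3)
        np.testing.assert_array_equal(a[0].ids, b[0].ids)
        np.testing.assert_array_equal(a[1].ids, b[1].ids)

    def test_partition_law(self, rng):
        ds = make_dataset(7, rng)
        train, test = split_dataset(ds, 0.5, seed=0)
        assert set(train.ids) | set(test.ids) == set(ds.ids)
        assert not set(train.ids) & set(test.ids)

    def test_small_class_rejected(self):
        ds = Dataset(
            vectors=np.zeros((3, 2)),
            labels=np.array(["healthy", "healthy", "celiac"]),
            ids=np.array(["a", "b", "c"]),
        )
        with pytest.raises(ValueError):
            split_dataset(ds, 0.5, seed=0)


def knn_oracle(X, y, query, k, weighted=False):
    """Exhaustive distance-sort reference predictor."""
    d = np.sqrt(((X - query) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    dk, yk = d[order], y[order]
    if weighted:
        if dk[0] == 0.0:
            return yk[0]
        scores = collections.defaultdict(float)
        for dist, lab in zip(dk, yk):
            scores[lab] += 1.0 / dist
        best = max(scores.values())
        winners = {lab for lab, s in scores.items() if s == best}
    else:
        votes = collections.Counter(yk)
        top = max(votes.values())
        winners = {lab for lab, v in votes.items() if v == top}
    for lab in yk:
        if lab in winners:
            return lab


class TestFineKNN:
    def test_exact_match_k1(self, rng):
        ds = make_dataset(5, rng)
        clf = fit_fine_knn(ds, k=1)
        assert clf.predict(ds.vectors[3])[0] == ds.labels[3]

    def test_majority_vote(self):
        X = np.array([[0.0], [0.1], [5.0]])
        y = np.array(["A", "A", "B"])
        clf = fit_fine_knn(Dataset(X, y, np.array(["a", "b", "c"])), k=3)
        assert clf.predict([[0.05]])[0] == "A"

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(20, 2))
            y = rng.choice(["healthy", "celiac"], size=20)
            if len(set(y)) < 2:
                continue
            clf = fit_fine_knn(Dataset(X, y, np.arange(20).astype(str)), k=3)
            query = rng.normal(size=2)
            assert clf.predict(query)[0] == knn_oracle(X, y, query, 3)

    def test_k_validated(self, rng):
        ds = make_dataset(2, rng)
        with pytest.raises(ValueError):
            fit_fine_knn(ds, k=0)
        with pytest.raises(ValueError):
            fit_fine_knn(ds, k=10)


class TestWeightedKNN:
    def test_two_near_beat_one_far(self):
        # k=3: two near neighbors of one class outweigh the third, farther one
        X = np.array([[0.1, 0.0], [-0.1, 0.0], [0.9, 0.0], [50.0, 50.0]])
        y = np.array(["R", "R", "G", "G"])
        clf = fit_weighted_knn(Dataset(X, y, np.array(list("abcd"))), k=3)
        assert clf.predict([[0.0, 0.0]])[0] == "R"

    def test_exact_match_short_circuits(self, rng):
        ds = make_dataset(5, rng)
        clf = fit_weighted_knn(ds, k=3)
        assert clf.predict(ds.vectors[0])[0] == ds.labels[0]

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(25, 3))
            y = rng.choice(["healthy", "celiac"], size=25)
            if len(set(y)) < 2:
                continue
            clf = fit_weighted_knn(Dataset(X, y, np.arange(25).astype(str)), k=3)
            query = rng.normal(size=3)
            assert clf.predict(query)[0] == knn_oracle(X, y, query, 3, weighted=True)


class TestLinearSVM:
    def test_separable_clusters_perfect_training_accuracy(self, rng):
        ds = make_dataset(10, rng, spread=0.3, gap=20.0)
        clf = fit_linear_svm(ds, seed=0)
        assert np.all(clf.predict(ds.vectors) == ds.labels)

    def test_mirrored_data_negates_decision_values(self, rng):
        ds = make_dataset(10, rng, spread=0.5, gap=8.0)
        clf = fit_linear_svm(ds, seed=0)
        flipped = Dataset(
            -ds.vectors,
            np.where(ds.labels == "healthy", "celiac", "healthy"),
            ds.ids,
        )
        clf2 = fit_linear_svm(flipped, seed=0)
        query = rng.normal(size=(5, 2))
        np.testing.assert_allclose(
            clf2.decision_function(-query), -clf.decision_function(query), atol=5e-2
        )

    def test_coef_has_training_dimension(self, rng):
        ds = make_dataset(5, rng)
        clf = fit_linear_svm(ds)
        assert clf.coef_.shape == (1, 2)

    def test_single_class_rejected(self):
        ds = Dataset(np.zeros((4, 2)), np.array(["healthy"] * 4), np.arange(4).astype(str))
        with pytest.raises(ValueError):
            fit_linear_svm(ds)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_classifier(make_dataset(5, rng), "deep_net")


class _StubClassifier:
    def __init__(self, predictions):
        self._pred = np.asarray(predictions)

    def predict(self, vectors):
        return self._pred


class TestEvaluate:
    def _dataset(self, labels):
        labels = np.asarray(labels)
        n = len(labels)
        return Dataset(np.zeros((n, 2)), labels, np.arange(n).astype(str))

    def test_all_correct(self):
        labels = ["celiac"] * 3 + ["healthy"] * 2
        report = evaluate(_StubClassifier(labels), self._dataset(labels))
        assert report.accuracy == 100.0
        assert report.f1 == 1.0

    def test_f1_formula_tp48_fp3(self):
        labels = ["celiac"] * 48 + ["healthy"] * 3
        preds = ["celiac"] * 51  # tp=48, fp=3, fn=0
        report = evaluate(_StubClassifier(preds), self._dataset(labels))
        assert report.tp == 48 and report.fp == 3 and report.fn == 0
        assert report.f1 == pytest.approx(48 / 49.5)

    def test_zero_sensibility(self):
        labels = ["celiac"] * 2 + ["healthy"] * 2
        preds = ["healthy"] * 4
        report = evaluate(_StubClassifier(preds), self._dataset(labels))
        assert report.sensibility == 0.0
        assert report.precision == 0.0 and report.precision_undefined

    def test_counts_partition_test_set(self, rng):
        labels = rng.choice(["healthy", "celiac"], size=17)
        preds = rng.choice(["healthy", "celiac"], size=17)
        report = evaluate(_StubClassifier(preds), self._dataset(labels))
        assert report.tp + report.fp + report.tn + report.fn == 17
        assert report.accuracy == pytest.approx(100.0 * (report.tp + report.tn) / 17)

    def test_f1_equals_harmonic_mean(self, rng):
        for _ in range(50):
            tp, fp, fn = rng.integers(1, 30, size=3)
            p = tp / (tp + fp)
            r = tp / (tp + fn)
            assert f1_from_counts(tp, fp, fn) == pytest.approx(2 * p * r / (p + r))

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_StubClassifier([]), self._dataset([]))


class TestMetricArithmetic:
    def test_accuracy_51_3(self):
        assert accuracy_from_counts(51, 3) == 94.1

    def test_accuracy_51_4(self):
        assert accuracy_from_counts(51, 4) == 92.2

    def test_zero_errors(self):
        assert accuracy_from_counts(37, 0) == 100.0

    @pytest.mark.parametrize("total,errors", [(0, 0), (5, 6), (5, -1)])
    def test_invalid_counts(self, total, errors):
        with pytest.raises(ValueError):
            accuracy_from_counts(total, errors)

    def test_dataset_bookkeeping(self):
        assert remaining_after_exclusion(109, 4) == 105

    @pytest.mark.parametrize(
        "p,r,expected",
        [(0.84, 0.80, 0.81), (0.92, 0.93, 0.92), (0.94, 0.96, 0.94)],
    )
    def test_truncated_f1_matches_report_table(self, p, r, expected):
        assert truncate2(2 * p * r / (p + r)) == expected


class TestDatasetFromTable:
    def test_roundtrip_from_feature_table(self, rng):
        summaries = [
            summarize_video([FrameFeatures(*rng.random(10)) for _ in range(3)])
            for _ in range(4)
        ]
        table = feature_table(
            ["a", "b", "c", "d"], ["healthy", "celiac", "healthy", "celiac"], summaries
        )
        ds = dataset_from_table(table)
        assert ds.vectors.shape == (4, 30)
        assert list(ds.ids) == ["a", "b", "c", "d"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            Dataset(np.zeros((2, 2)), np.array(["healthy", "celiac"]), np.array(["x", "x"]))
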