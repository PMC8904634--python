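"""Classifiers and evaluation metrics for the per-video feature table.

Three lightweight models are supported: fine KNN (k=3 majority vote),
distance-weighted KNN (inverse-distance vote), and a linear hinge-loss SVM
with balanced class weights.  The positive class for precision / sensibility
/ F1 is ``celiac``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .features import FEATURE_NAMES, SUMMARY_STATS

__all__ = [
    "CLASSIFIER_KINDS",
    "Dataset",
    "EvaluationReport",
    "FineKNN",
    "WeightedKNN",
    "LinearSVM",
    "standardize",
    "apply_standardization",
    "dataset_from_table",
    "split_dataset",
    "fit_classifier",
    "fit_fine_knn",
    "fit_weighted_knn",
    "fit_linear_svm",
    "evaluate",
    "accuracy_from_counts",
    "remaining_after_exclusion",
    "f1_from_counts",
    "truncate2",
]

CLASSIFIER_KINDS = ("fine_knn", "weighted_knn", "linear_svm")
POSITIVE_CLASS = "celiac"


@dataclass
class Dataset:
    """Feature vectors, class labels and video ids of equal length."""

    vectors: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) strings
    ids: np.ndarray  # (n,) strings

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels)
        self.ids = np.asarray(self.ids)
        n = len(self.vectors)
        if len(self.labels) != n or len(self.ids) != n:
            raise ValueError("vectors, labels and ids must have equal length")
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate video ids in dataset")

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class EvaluationReport:
    """Confusion counts plus derived metrics (accuracy in percent)."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    sensibility: float
    f1: float
    precision_undefined: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def dataset_from_table(table: pd.DataFrame) -> Dataset:
    """Extract the numeric feature matrix from a feature-table DataFrame."""
    columns = [f"{n}_{s}" for n in FEATURE_NAMES for s in SUMMARY_STATS]
    return Dataset(
        vectors=table[columns].to_numpy(dtype=float),
        labels=table["label"].to_numpy(),
        ids=table["video_id"].astype(str).to_numpy(),
    )


def standardize(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores; constant columns map to zero.

    Returns ``(scaled, mean, std)`` so the training-set parameters can be
    re-applied to held-out data.
    """
    vectors = np.asarray(vectors, dtype=float)
    if len(vectors) < 2:
        raise ValueError("standardization needs at least 2 rows")
    mean = vectors.mean(axis=0)
    std = vectors.std(axis=0)
    return apply_standardization(vectors, mean, std), mean, std


def apply_standardization(
    vectors: np.ndarray, mean: np.ndarray, std: np.ndarray
) -> np.ndarray:
    safe = np.where(std == 0.0, 1.0, std)
    out = (np.asarray(vectors, dtype=float) - mean) / safe
    out[:, std == 0.0] = 0.0
    return out


def split_dataset(
    ds: Dataset, train_fraction: float = 0.5, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Stratified random train/test split, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(ds.labels):
        members = np.flatnonzero(ds.labels == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        members = rng.permutation(members)
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    train_idx.sort()
    test_idx.sort()

    def _take(idx: list[int]) -> Dataset:
        return Dataset(ds.vectors[idx], ds.labels[idx], ds.ids[idx])

    return _take(train_idx), _take(test_idx)


class FineKNN:
    """k-nearest-neighbor majority vote with Euclidean distance.

    Ties (equal vote counts) go to the class of the nearest neighbor among
    the tied classes, which makes prediction deterministic for a fixed
    training order.
    """

    kind = "fine_knn"

    def __init__(self, k: int = 3):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, vectors: np.ndarray, labels: np.ndarray) -> "FineKNN":
        vectors = np.asarray(vectors, dtype=float)
        if self.k > len(vectors):
            raise ValueError("k exceeds training-set size")
        self._X = vectors
        self._y = np.asarray(labels)
        return self

    def _neighbors(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.linalg.norm(self._X - x, axis=1)
        order = np.argsort(d, kind="stable")[: self.k]
        return d[order], self._y[order]

    def _predict_one(self, x: np.ndarray) -> str:
        dists, labels = self._neighbors(x)
        classes, votes = np.unique(labels, return_counts=True)
        winners = classes[votes == votes.max()]
        if len(winners) == 1:
            return winners[0]
        for lab in labels:  # labels are distance-sorted
            if lab in winners:
                return lab
        raise AssertionError("unreachable")

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        return np.array([self._predict_one(x) for x in vectors])


class WeightedKNN(FineKNN):
    """KNN voting by summed inverse distances of the k nearest neighbors.

    A zero-distance neighbor (exact training match) short-circuits to its
    own label.
    """

    kind = "weighted_knn"

    def _predict_one(self, x: np.ndarray) -> str:
        dists, labels = self._neighbors(x)
        if dists[0] == 0.0:
            return labels[0]
        weights: dict[str, float] = {}
        for d, lab in zip(dists, labels):
            weights[lab] = weights.get(lab, 0.0) + 1.0 / d
        best = max(weights.values())
        winners = {lab for lab, wt in weights.items() if wt == best}
        if len(winners) == 1:
            return winners.pop()
        for lab in labels:
            if lab in winners:
                return lab
        raise AssertionError("unreachable")


class LinearSVM:
    """Linear hinge-loss SVM with balanced class weights (tol 1e-3)."""

    kind = "linear_svm"

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def fit(self, vectors: np.ndarray, labels: np.ndarray) -> "LinearSVM":
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("SVM training requires both classes")
        self._svc = LinearSVC(
            loss="hinge",
            dual=True,
            tol=1e-3,
            C=self.C,
            class_weight="balanced",
            fit_intercept=True,
            random_state=self.seed,
            max_iter=100_000,
        )
        self._svc.fit(np.asarray(vectors, dtype=float), labels)
        return self

    @property
    def coef_(self) -> np.ndarray:
        return self._svc.coef_

    @property
    def intercept_(self) -> np.ndarray:
        return self._svc.intercept_

    def decision_function(self, vectors: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(np.atleast_2d(np.asarray(vectors, dtype=float)))

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return self._svc.predict(np.atleast_2d(np.asarray(vectors, dtype=float)))


def fit_fine_knn(train: Dataset, k: int = 3) -> FineKNN:
    return FineKNN(k=k).fit(train.vectors, train.labels)


def fit_weighted_knn(train: Dataset, k: int = 3) -> WeightedKNN:
    return WeightedKNN(k=k).fit(train.vectors, train.labels)


def fit_linear_svm(train: Dataset, C: float = 1.0, seed: int = 0) -> LinearSVM:
    return LinearSVM(C=C, seed=seed).fit(train.vectors, train.labels)


def fit_classifier(train: Dataset, kind: str, k: int = 3, C: float = 1.0, seed: int = 0):
    if kind == "fine_knn":
        return fit_fine_knn(train, k=k)
    if kind == "weighted_knn":
        return fit_weighted_knn(train, k=k)
    if kind == "linear_svm":
        return fit_linear_svm(train, C=C, seed=seed)
    raise ValueError(f"unknown classifier kind: {kind!r} (choose from {CLASSIFIER_KINDS})")


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = tp / (tp + (fp + fn) / 2); zero when the denominator vanishes."""
    denom = tp + 0.5 * (fp + fn)
    return tp / denom if denom > 0 else 0.0


def evaluate(
    clf, test: Dataset, positive_class: str = POSITIVE_CLASS
) -> EvaluationReport:
    """Confusion counts and metrics on a test split (accuracy in percent)."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = clf.predict(test.vectors)
    actual_pos = test.labels == positive_class
    pred_pos = pred == positive_class
    tp = int(np.sum(actual_pos & pred_pos))
    fp = int(np.sum(~actual_pos & pred_pos))
    tn = int(np.sum(~actual_pos & ~pred_pos))
    fn = int(np.sum(actual_pos & ~pred_pos))
    precision_undefined = (tp + fp) == 0
    precision = 0.0 if precision_undefined else tp / (tp + fp)
    sensibility = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return EvaluationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=100.0 * (tp + tn) / len(test),
        precision=precision,
        sensibility=sensibility,
        f1=f1_from_counts(tp, fp, fn),
        precision_undefined=precision_undefined,
    )


def accuracy_from_counts(total: int, errors: int) -> float:
    """Accuracy percentage from test size and error count, to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= errors <= total:
        raise ValueError("errors must lie in [0, total]")
    return round(100.0 * (total - errors) / total, 1)


def remaining_after_exclusion(initial: int = 109, excluded: int = 4) -> int:
    """Dataset bookkeeping: videos left after exclusions."""
    if excluded < 0 or excluded > initial:
        raise ValueError("excluded must lie in [0, initial]")
    return initial - excluded


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, e.g. 0.819 -> 0.81."""
    return math.floor(x * 100.0) / 100.0
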