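"""Vote-based K-nearest-neighbour diagnosis rule.

A query recording s is assigned the class c_i maximising

    score(s, c_i) = sum over the K nearest training rows S_j of
                    sim(s, S_j) * delta(S_j, c_i),

where delta is +1 when S_j belongs to c_i and -1 otherwise.  The similarity
weight is the constant 1 (an unweighted vote; with K = 1, the operating
point used for screening, any positive weight is equivalent).  Distances are
Euclidean by default (Manhattan available).  Deterministic tie rules:
equidistant training rows are ranked by lower row index; tied class scores
go to the positive (PD) class — the conservative call for a screening tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataset import LabeledDataset

__all__ = ["NeighborScore", "VoteKNN", "fit", "score", "predict"]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass(frozen=True)
class NeighborScore:
    """Per-class vote totals and the neighbours behind one prediction."""

    class_scores: dict[int, float]
    neighbor_indices: np.ndarray
    predicted: int

    def __post_init__(self) -> None:
        best = max(self.class_scores.values())
        if self.class_scores[self.predicted] != best:
            raise ValueError("predicted class must attain the maximal score")


class VoteKNN(ClassifierMixin, BaseEstimator):
    """Scikit-learn classifier implementing the signed-vote KNN rule."""

    def __init__(
        self,
        n_neighbors: int = 1,
        metric: str = "euclidean",
        positive_label: int = 1,
    ) -> None:
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.positive_label = positive_label

    def fit(self, X, y) -> "VoteKNN":
        """Store the training data verbatim (instance-based, no parameters)."""
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {self.metric!r}")
        X, y = check_X_y(X, y)
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.n_neighbors > X.shape[0]:
            raise ValueError(
                f"n_neighbors={self.n_neighbors} exceeds the {X.shape[0]} training rows"
            )
        self.X_ = np.asarray(X, dtype=np.float64)
        self.y_ = np.asarray(y)
        self.classes_ = np.unique(self.y_)
        self.n_features_in_ = X.shape[1]
        return self

    def _neighbor_indices(self, X: np.ndarray, k: int) -> np.ndarray:
        distances = cdist(X, self.X_, metric=_METRICS[self.metric])
        # stable argsort ranks exact distance ties by lower training-row index
        return np.argsort(distances, axis=1, kind="stable")[:, :k]

    def decision_scores(self, X, n_neighbors: int | None = None) -> np.ndarray:
        """Vote totals, one column per class in ``classes_`` order."""
        check_is_fitted(self, "X_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} features, classifier was fitted with {self.n_features_in_}"
            )
        k = self.n_neighbors if n_neighbors is None else n_neighbors
        if k > self.X_.shape[0]:
            raise ValueError(f"n_neighbors={k} exceeds the {self.X_.shape[0]} training rows")
        idx = self._neighbor_indices(X, k)
        neighbor_labels = self.y_[idx]
        scores = np.empty((X.shape[0], self.classes_.size))
        for j, cls in enumerate(self.classes_):
            member = neighbor_labels == cls
            scores[:, j] = member.sum(axis=1) - (~member).sum(axis=1)
        return scores

    def predict(self, X) -> np.ndarray:
        """Class with the maximal vote; ties resolved to the positive class."""
        scores = self.decision_scores(X)
        best = scores.max(axis=1)
        out = np.empty(scores.shape[0], dtype=self.y_.dtype)
        for i in range(scores.shape[0]):
            tied = self.classes_[scores[i] == best[i]]
            if self.positive_label in tied:
                out[i] = self.positive_label
            else:
                out[i] = tied[0]
        return out

    def score_record(self, query: np.ndarray) -> NeighborScore:
        """Full vote breakdown for a single query vector."""
        query = np.atleast_2d(np.asarray(query, dtype=np.float64))
        scores = self.decision_scores(query)[0]
        idx = self._neighbor_indices(query, self.n_neighbors)[0]
        predicted = self.predict(query)[0]
        return NeighborScore(
            class_scores={int(c): float(s) for c, s in zip(self.classes_, scores)},
            neighbor_indices=idx,
            predicted=int(predicted),
        )


# ---------------------------------------------------------------------------
# functional wrappers over the estimator


def fit(train: LabeledDataset, n_neighbors: int = 1, metric: str = "euclidean") -> VoteKNN:
    """Fit the vote rule on a labelled dataset."""
    return VoteKNN(n_neighbors=n_neighbors, metric=metric).fit(train.features, train.labels)


def score(clf: VoteKNN, query: np.ndarray, c_i: int, n_neighbors: int | None = None) -> float:
    """Vote total of class ``c_i`` for one query."""
    scores = clf.decision_scores(np.atleast_2d(query), n_neighbors=n_neighbors)[0]
    (j,) = np.where(clf.classes_ == c_i)
    if j.size == 0:
        raise ValueError(f"class {c_i!r} not present in the training data")
    return float(scores[j[0]])


def predict(clf: VoteKNN, query: np.ndarray) -> tuple[int, NeighborScore]:
    """Predicted label plus the neighbour breakdown for one query."""
    record = clf.score_record(query)
    return record.predicted, record
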