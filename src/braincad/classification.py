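"""Binary classifiers for the healthy (-1) / pathological (+1) decision.

GentleBoost is implemented here in full: each round fits a small regression
tree to the labels under the current example weights; a leaf (region)
response is the weighted mean of the +/-1 labels inside it,

    h(region) = (g+ - g-) / (g+ + g-)   in [-1, 1],

where ``g+``/``g-`` are the summed weights of positive/negative examples in
the region.  Weights are then multiplied by ``exp(-y h(x))`` — misclassified
examples gain weight — and renormalized to sum to one.  The strong classifier
is the sign of the summed round responses.

KNN is implemented directly (3-nearest-neighbor Euclidean majority vote);
the soft-margin RBF SVM and the 100-tree random forest delegate to
scikit-learn under fixed hyperparameter contracts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ClassifierSpec",
    "GentleBoost",
    "KNearestNeighbors",
    "train_gentleboost",
    "predict_gentleboost",
    "train_classifier",
]


def _validate_training_data(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("labels must be -1 (healthy) or +1 (pathological)")
    if not np.isfinite(X).all():
        raise ValueError("features contain missing or non-finite values")
    y = y.astype(np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    return X, y


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier choice plus the fixed hyperparameter contract.

    * ``svm_rbf`` — soft-margin SVM with RBF kernel ``exp(-alpha |u - v|^2)``;
      ``svm_alpha=None`` means ``1 / n_features``.
    * ``knn`` — k-nearest-neighbor Euclidean majority vote, k odd.
    * ``rf`` — 100-tree bagged random forest.
    * ``gentleboost`` — 100 rounds of depth-limited regression trees.
    """

    kind: Literal["svm_rbf", "knn", "rf", "gentleboost"] = "rf"
    svm_alpha: float | None = None
    svm_cost: float = 1.0
    knn_k: int = 3
    rf_trees: int = 100
    gb_rounds: int = 100
    gb_max_splits: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "knn", "rf", "gentleboost"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.svm_alpha is not None and self.svm_alpha <= 0:
            raise ValueError("svm_alpha must be positive")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be a positive odd integer")
        if min(self.rf_trees, self.gb_rounds) < 0 or self.gb_max_splits < 1:
            raise ValueError("invalid ensemble size")


class GentleBoost:
    """GentleBoost ensemble of weighted regression trees.

    Parameters
    ----------
    rounds
        Number of boosting rounds ``V``.
    max_splits
        Maximum number of splits per weak tree (so at most ``max_splits + 1``
        regions).
    """

    def __init__(self, rounds: int = 100, max_splits: int = 10, random_state: int = 0):
        self.rounds = rounds
        self.max_splits = max_splits
        self.random_state = random_state
        self.trees_: list[DecisionTreeRegressor] = []
        self.weight_history_: list[float] = []  # normalizer W_v of each round
        self.weight_sums_: list[float] = []  # post-normalization sums (== 1)
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GentleBoost":
        X, y = _validate_training_data(X, y)
        P = X.shape[0]
        self.n_features_ = X.shape[1]
        g = np.full(P, 1.0 / P)
        self.trees_ = []
        self.weight_history_ = []
        self.weight_sums_ = []
        yf = y.astype(np.float64)
        for _ in range(self.rounds):
            tree = DecisionTreeRegressor(
                max_leaf_nodes=self.max_splits + 1, random_state=self.random_state
            )
            tree.fit(X, yf, sample_weight=g)
            self.trees_.append(tree)
            h = tree.predict(X)
            g = g * np.exp(-yf * h)
            total = g.sum()
            self.weight_history_.append(float(total))
            if not np.isfinite(total) or total <= 0.0:
                # numeric underflow: keep the rounds trained so far
                import warnings

                warnings.warn("GentleBoost weights underflowed; training halted early")
                break
            g = g / total
            self.weight_sums_.append(float(g.sum()))
        return self

    def region_responses(self) -> list[np.ndarray]:
        """Per-round leaf (region) responses; each value lies in [-1, 1]."""
        out = []
        for tree in self.trees_:
            leaves = tree.tree_.children_left == -1
            out.append(tree.tree_.value[leaves, 0, 0].copy())
        return out

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if self.n_features_ is not None and X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1]}"
            )
        margin = np.zeros(X.shape[0])
        for tree in self.trees_:
            margin += tree.predict(X)
        return margin

    def predict(self, X: np.ndarray) -> np.ndarray:
        margin = self.decision_function(X)
        # zero margin resolves to pathological: fail-safe toward sensitivity
        return np.where(margin >= 0, 1, -1).astype(np.int64)

    def save(self, path: str | Path) -> None:
        """Persist the ensemble as inspectable JSON (splits and responses)."""
        rounds = []
        for tree in self.trees_:
            t = tree.tree_
            rounds.append(
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "response": t.value[:, 0, 0].tolist(),
                }
            )
        payload = {
            "rounds": rounds,
            "max_splits": self.max_splits,
            "n_features": self.n_features_,
        }
        Path(path).write_text(json.dumps(payload))


class KNearestNeighbors:
    """k-nearest-neighbor Euclidean majority vote, implemented directly."""

    def __init__(self, k: int = 3):
        if k < 1 or k % 2 == 0:
            raise ValueError("k must be a positive odd integer")
        self.k = k
        self.X_: np.ndarray | None = None
        self.y_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNearestNeighbors":
        X, y = _validate_training_data(X, y)
        if X.shape[0] < self.k:
            raise ValueError(f"need at least k={self.k} training points")
        self.X_, self.y_ = X, y
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        d2 = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        # stable sort so distance ties resolve toward earlier training rows
        order = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        votes = self.y_[order].sum(axis=1)
        return np.where(votes >= 0, 1, -1).astype(np.int64)


def train_gentleboost(
    X: np.ndarray, y: np.ndarray, rounds: int = 100, max_splits: int = 10
) -> GentleBoost:
    """Train a GentleBoost ensemble (functional wrapper around the class)."""
    return GentleBoost(rounds=rounds, max_splits=max_splits).fit(X, y)


def predict_gentleboost(model: GentleBoost, x: np.ndarray) -> tuple[int, float]:
    """Predict one feature vector; returns ``(label, margin)``."""
    margin = float(model.decision_function(np.atleast_2d(x))[0])
    return (1 if margin >= 0 else -1), margin


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Train the classifier named by ``spec``; returns an object with
    ``predict(X) -> labels in {-1, +1}``."""
    X, y = _validate_training_data(X, y)
    if spec.kind == "svm_rbf":
        gamma = spec.svm_alpha if spec.svm_alpha is not None else 1.0 / X.shape[1]
        return SVC(kernel="rbf", gamma=gamma, C=spec.svm_cost).fit(X, y)
    if spec.kind == "knn":
        return KNearestNeighbors(k=spec.knn_k).fit(X, y)
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=spec.rf_trees, random_state=seed
        ).fit(X, y)
    return GentleBoost(rounds=spec.gb_rounds, max_splits=spec.gb_max_splits).fit(X, y)
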