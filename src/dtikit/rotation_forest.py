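"""Rotation Forest: a tree ensemble over per-tree PCA-rotated feature space.

Each tree is trained on the data multiplied by a sparse block-diagonal
rotation matrix.  The blocks are principal-component axes computed, per
random feature subset, on a 75% sample of the training rows drawn
without replacement, so that every tree sees a different orthonormal
rotation of the full feature space.  Class confidences are the average
of the trees' probability estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier


@dataclass(frozen=True)
class RotationForestConfig:
    """Ensemble size L, feature-subset size, row-sample fraction and seed."""

    n_trees: int = 35
    subset_size: int = 3
    bootstrap_fraction: float = 0.75
    with_replacement: bool = False
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")


@dataclass
class RotatedTree:
    """One ensemble member: feature partition, rotation matrix, fitted tree."""

    partition: list[np.ndarray]
    rotation: np.ndarray
    tree: DecisionTreeClassifier


@dataclass
class RotationForestModel:
    trees: list[RotatedTree]
    classes: np.ndarray
    n_features: int
    config: RotationForestConfig = field(default=RotationForestConfig())


def _principal_axes(rows: np.ndarray) -> np.ndarray:
    """Orthonormal principal axes (columns, descending variance) of a sample.

    Uses the eigendecomposition of the sample covariance, which yields a
    full orthonormal basis even when the sample is rank deficient.  A
    zero-variance sample gets the identity (PCA is undefined there but
    the rotation must stay invertible).  Axis signs are fixed so the
    largest-magnitude component of each axis is positive, making the
    rotation deterministic.
    """
    d = rows.shape[1]
    centered = rows - rows.mean(axis=0)
    cov = centered.T @ centered
    if not np.any(cov):
        return np.eye(d)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order]
    flip = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    return axes * flip


def fit(X: np.ndarray, y: np.ndarray, config: RotationForestConfig = RotationForestConfig()) -> RotationForestModel:
    """Fit a Rotation Forest.

    Per tree: feature indices are randomly partitioned into subsets of
    ~``subset_size``; per subset, principal axes of a seeded 75% row
    sample form one diagonal block of the rotation matrix R; the tree is
    then trained on X @ R against the full label vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("rotation forest needs at least two classes in y")
    if d < 1:
        raise ValueError("rotation forest needs at least one feature")
    rng = np.random.default_rng(config.seed)
    n_sample = int(np.ceil(config.bootstrap_fraction * n))

    trees: list[RotatedTree] = []
    for i in range(config.n_trees):
        perm = rng.permutation(d)
        n_subsets = max(1, d // config.subset_size)
        partition = [np.sort(part) for part in np.array_split(perm, n_subsets)]
        R = np.zeros((d, d))
        for subset in partition:
            rows = rng.choice(n, size=n_sample, replace=config.with_replacement)
            R[np.ix_(subset, subset)] = _principal_axes(X[np.ix_(rows, subset)])
        tree = DecisionTreeClassifier(
            max_depth=config.max_depth,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X @ R, y)
        trees.append(RotatedTree(partition, R, tree))
    return RotationForestModel(trees, classes, d, config)


def predict_proba(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Average class-probability estimates of the rotated trees.

    Returns an (n_samples, n_classes) matrix whose rows sum to 1,
    columns ordered as ``model.classes``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns but the model was trained on {model.n_features}"
        )
    scores = np.zeros((X.shape[0], model.classes.size))
    for member in model.trees:
        proba = member.tree.predict_proba(X @ member.rotation)
        # tree class order may be a subset/reorder of the model's classes
        cols = np.searchsorted(model.classes, member.tree.classes_)
        scores[:, cols] += proba
    return scores / len(model.trees)


def predict(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Arg-max class per sample; ties resolve to the smaller class label."""
    proba = predict_proba(model, X)
    return model.classes[np.argmax(proba, axis=1)]


class RotationForest:
    """Estimator-style wrapper around :func:`fit` / :func:`predict_proba`."""

    def __init__(self, config: RotationForestConfig = RotationForestConfig()):
        self.config = config
        self.model_: RotationForestModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RotationForest":
        self.model_ = fit(X, y, self.config)
        return self

    def _require_fitted(self) -> RotationForestModel:
        if self.model_ is None:
            raise ValueError("RotationForest is not fitted")
        return self.model_

    @property
    def classes_(self) -> np.ndarray:
        return self._require_fitted().classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self._require_fitted(), X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self._require_fitted(), X)

    def positive_scores(self, X: np.ndarray) -> np.ndarray:
        """Confidence of the largest class label (the positive class for 0/1)."""
        return self.predict_proba(X)[:, -1]
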