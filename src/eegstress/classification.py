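"""Euclidean k-NN with stratified splitting and CV-based k selection.

The neighbour count k is chosen from an odd candidate list (1, 3, ..., 19)
by stratified 10-fold cross-validation on the training split, minimizing
mean misclassification error (ties go to the smallest k).  Tie-breaking in
prediction is deterministic: equal votes fall back to the class of the
single nearest neighbour, and equal distances at the k-th position are
resolved toward the lower training-row index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import DimensionError

logger = logging.getLogger(__name__)


@dataclass
class KnnConfig:
    k_candidates: list[int] = field(
        default_factory=lambda: list(range(1, 20, 2))
    )
    cv_folds: int = 10
    train_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.k_candidates):
            raise ValueError("k candidates must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class CVResult:
    k_candidates: list[int]
    mean_errors: np.ndarray  # per candidate, mean over folds
    chosen_k: int


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def split(
    X: np.ndarray, y: np.ndarray, cfg: KnnConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified random train/test split at the configured ratio."""
    cfg = cfg or KnnConfig()
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows to split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        np.asarray(X, dtype=float),
        y,
        train_size=cfg.train_fraction,
        stratify=y,
        random_state=cfg.seed,
    )
    return X_tr, X_te, y_tr, y_te


def knn_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority-vote k-NN with deterministic tie-breaking."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    y_train = np.asarray(y_train)
    if k > len(X_train):
        raise ValueError(f"k={k} exceeds {len(X_train)} training rows")
    dist = cdist(X_query, X_train)
    # stable sort: equal distances resolve to the lower training index
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    neigh_labels = y_train[order]

    classes = np.unique(y_train)
    votes = np.stack(
        [(neigh_labels == c).sum(axis=1) for c in classes], axis=1
    )
    top = votes.max(axis=1)
    winner = classes[votes.argmax(axis=1)]
    # vote tie -> class of the single nearest neighbour
    tied = (votes == top[:, None]).sum(axis=1) > 1
    winner[tied] = neigh_labels[tied, 0]
    return winner


def select_k(
    X: np.ndarray, y: np.ndarray, cfg: KnnConfig | None = None
) -> CVResult:
    """Pick k by stratified K-fold CV, minimizing misclassification error."""
    cfg = cfg or KnnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    folds = cfg.cv_folds
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
        logger.warning(
            "too few rows per class for %d folds; using %d", cfg.cv_folds, folds
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))
    max_train = min(len(tr) for tr, _ in splits)
    candidates = [k for k in cfg.k_candidates if k <= max_train]
    errors = np.zeros(len(candidates))
    for i, k in enumerate(candidates):
        fold_err = [
            float(np.mean(knn_predict(X[tr], y[tr], X[va], k) != y[va]))
            for tr, va in splits
        ]
        errors[i] = float(np.mean(fold_err))
    chosen = candidates[int(np.argmin(errors))]  # argmin ties -> smallest k
    return CVResult(k_candidates=candidates, mean_errors=errors, chosen_k=chosen)
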