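"""Synthetic minority over-sampling (SMOTE) on feature rows.

New minority samples are drawn on segments between a minority row and one
of its k nearest minority neighbours (Euclidean):  s = x_i + u (x_nn - x_i)
with u ~ U(0, 1).  Majority rows are never touched; originals are retained
first in the output, synthetic rows appended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority target as a fraction of majority
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0.0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must be in (0, 1]")


def smote(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class up to ``target_ratio`` x majority."""
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) != 2:
        raise ValueError("smote expects binary labels")
    minority = labels[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    target = int(round(cfg.target_ratio * n_maj))
    n_new = target - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("cannot oversample a class with fewer than 2 rows")

    k = cfg.k_neighbors
    if n_min <= k:
        k = n_min - 1
        logger.warning(
            "minority count %d <= k_neighbors; reducing k to %d", n_min, k
        )

    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(X_min), size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    anchors = X_min[base]
    partners = X_min[neigh[base, pick]]
    synthetic = anchors + u[:, None] * (partners - anchors)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out
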