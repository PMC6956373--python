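"""All-relevant feature ranking with a shadow-feature wrapper (Boruta).

Each iteration appends a freshly row-shuffled "shadow" copy of every
feature (carrying its marginal distribution but no label association),
fits a random forest on the extended block, and scores every column with a
permutation-importance Z score: for each tree, the out-of-bag accuracy
loss under within-tree permutation of the column, Z = mean(loss)/sd(loss)
over trees.  An original feature scores a "hit" whenever its Z exceeds the
best shadow Z of that iteration.  After the iteration budget, a one-sided
binomial test against p = 0.5 declares each feature confirmed, rejected,
or tentative; the selected set is the confirmed features.

This is all-relevant (not minimal-optimal) selection: a feature carrying
label information is kept even if another feature makes it redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier


@dataclass
class BorutaConfig:
    n_iterations: int = 20
    rf_trees: int = 100
    significance_alpha: float = 0.05
    importance: str = "permutation"  # or "mdi"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.significance_alpha < 1.0):
            raise ValueError("significance_alpha must be in (0, 1)")
        if self.importance not in ("permutation", "mdi"):
            raise ValueError("importance must be 'permutation' or 'mdi'")


@dataclass
class BorutaResult:
    feature_names: list[str]
    status: dict[str, str]  # confirmed / rejected / tentative
    hits: np.ndarray  # per feature
    z_history: np.ndarray  # (n_iterations, n_features) original-feature Z
    mzsf_history: np.ndarray  # per-iteration max shadow Z
    n_iterations: int = 0

    @property
    def confirmed(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == "confirmed"]

    @property
    def rejected(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == "rejected"]

    @property
    def tentative(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == "tentative"]


def make_shadow(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Append an independently row-shuffled copy of every column."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one column")
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to shuffle shadows")
    shadow = np.column_stack(
        [rng.permutation(X[:, j]) for j in range(X.shape[1])]
    )
    return np.hstack([X, shadow])


def _oob_mask(tree_seed: int, n: int) -> np.ndarray:
    # sklearn draws each tree's bootstrap as RandomState(seed).randint(0, n, n)
    sampled = np.random.RandomState(tree_seed).randint(0, n, n)
    mask = np.ones(n, dtype=bool)
    mask[sampled] = False
    return mask


def _fit_forest(
    X: np.ndarray, y: np.ndarray, cfg: BorutaConfig, seed: int
) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=cfg.rf_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def importance_z(
    X: np.ndarray,
    y: np.ndarray,
    cfg: BorutaConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-importance Z score per column of ``X``.

    For every tree: accuracy on its out-of-bag rows, minus accuracy after
    permuting one column among those rows; Z = mean / population-sd of the
    per-tree losses (0 where the sd vanishes, e.g. constant columns).
    """
    cfg = cfg or BorutaConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if cfg.importance == "mdi":
        return _mdi_z(X, y, cfg, seed)

    rf = _fit_forest(X, y, cfg, seed)
    n, p = X.shape
    classes = rf.classes_
    rng = np.random.default_rng(seed)
    losses = np.full((cfg.rf_trees, p), np.nan)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for t, est in enumerate(rf.estimators_):
        oob = _oob_mask(est.random_state, n)
        if oob.sum() < 2:
            continue
        Xo = X32[oob]
        yo = y[oob]
        tree = est.tree_

        def _pred(arr: np.ndarray) -> np.ndarray:
            out = tree.predict(arr)
            if out.ndim == 3:  # (n, n_outputs, n_classes) in some versions
                out = out[:, 0]
            return classes[out.argmax(axis=1)]

        base_acc = float(np.mean(_pred(Xo) == yo))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = _pred(Xp)
            losses[t, j] = base_acc - float(np.mean(pred == yo))
    mean = np.nanmean(losses, axis=0)
    sd = np.nanstd(losses, axis=0)
    z = np.zeros(p)
    nonzero = sd > 0
    z[nonzero] = mean[nonzero] / sd[nonzero]
    return z


def _mdi_z(
    X: np.ndarray, y: np.ndarray, cfg: BorutaConfig, seed: int
) -> np.ndarray:
    """Mean-decrease-impurity engine behind the same Z interface."""
    rf = _fit_forest(X, y, cfg, seed)
    imp = np.array([est.feature_importances_ for est in rf.estimators_])
    mean = imp.mean(axis=0)
    sd = imp.std(axis=0)
    z = np.zeros(X.shape[1])
    nonzero = sd > 0
    z[nonzero] = mean[nonzero] / sd[nonzero]
    return z


def boruta_rank(
    X: np.ndarray,
    y: np.ndarray,
    cfg: BorutaConfig | None = None,
    feature_names: list[str] | None = None,
) -> BorutaResult:
    """Run the shadow-feature wrapper and classify every feature."""
    cfg = cfg or BorutaConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    names = feature_names or [f"F{i + 1}" for i in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length mismatch")

    rng = np.random.default_rng(cfg.seed)
    hits = np.zeros(p, dtype=int)
    z_hist = np.zeros((cfg.n_iterations, p))
    mzsf_hist = np.zeros(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        extended = make_shadow(X, rng)
        rf_seed = int(rng.integers(2**31 - 1))
        z = importance_z(extended, y, cfg, seed=rf_seed)
        z_orig, z_shadow = z[:p], z[p:]
        mzsf = float(z_shadow.max())
        hits += (z_orig > mzsf).astype(int)
        z_hist[it] = z_orig
        mzsf_hist[it] = mzsf

    status: dict[str, str] = {}
    for name, h in zip(names, hits):
        if binomtest(int(h), cfg.n_iterations, 0.5, alternative="greater").pvalue < cfg.significance_alpha:
            status[name] = "confirmed"
        elif binomtest(int(h), cfg.n_iterations, 0.5, alternative="less").pvalue < cfg.significance_alpha:
            status[name] = "rejected"
        else:
            status[name] = "tentative"
    return BorutaResult(
        feature_names=list(names),
        status=status,
        hits=hits,
        z_history=z_hist,
        mzsf_history=mzsf_hist,
        n_iterations=cfg.n_iterations,
    )
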