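"""Method variants, accuracy metrics, ANOVA comparison and PCA projection.

Three classification pipelines share the same feature pool and k-NN
back end and differ only in the feature-reduction stage:

* ``proposed``          — Boruta-confirmed features,
* ``pca_knn``           — PCA projection (default 2 components),
* ``all_features_knn``  — no reduction.

Class-wise accuracy follows the convention 100 * TP_c / (TP_c + FP_c) with
the class of interest as positive — i.e. per-class precision; per-class
recall is reported alongside.  Average accuracy is 100 * (TP + TN) / total.
One-way fixed-effects ANOVA compares per-dataset accuracies across methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .balancing import SmoteConfig, smote
from .classification import KnnConfig, knn_predict, select_k, split
from .deap_io import ParticipantDataset
from .feature_pool import FEATURE_NAMES, extract_features, feature_matrix
from .feature_selection import BorutaConfig, boruta_rank

logger = logging.getLogger(__name__)

VARIANTS = ("proposed", "pca_knn", "all_features_knn")

#: label codes of the two states (stress is the positive class)
CALM, STRESS = 0, 1


@dataclass(frozen=True)
class Confusion:
    """Binary confusion counts with stress (label 1) as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> Confusion:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return Confusion(
        tp=int(np.sum((y_pred == STRESS) & (y_true == STRESS))),
        fp=int(np.sum((y_pred == STRESS) & (y_true == CALM))),
        tn=int(np.sum((y_pred == CALM) & (y_true == CALM))),
        fn=int(np.sum((y_pred == CALM) & (y_true == STRESS))),
    )


def classwise_accuracy(conf: Confusion, cls: int) -> float:
    """Per-class accuracy 100 * TP_c / (TP_c + FP_c), with ``cls`` positive.

    Returns NaN (undefined-metric marker) when the class was never
    predicted.
    """
    if cls == STRESS:
        tp, fp = conf.tp, conf.fp
    elif cls == CALM:
        tp, fp = conf.tn, conf.fn
    else:
        raise ValueError(f"unknown class {cls}")
    if tp + fp == 0:
        return float("nan")
    return 100.0 * tp / (tp + fp)


def classwise_recall(conf: Confusion, cls: int) -> float:
    """Per-class recall 100 * TP_c / (TP_c + FN_c), reported for clarity."""
    if cls == STRESS:
        tp, fn = conf.tp, conf.fn
    elif cls == CALM:
        tp, fn = conf.tn, conf.fp
    else:
        raise ValueError(f"unknown class {cls}")
    if tp + fn == 0:
        return float("nan")
    return 100.0 * tp / (tp + fn)


def average_accuracy(conf: Confusion) -> float:
    """Overall accuracy 100 * (TP + TN) / total."""
    if conf.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (conf.tp + conf.tn) / conf.total


def pca_project(
    X: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the correlation-scaled feature matrix.

    Columns are z-scored before the eigendecomposition, and each
    component's sign is fixed so its largest-magnitude loading is
    positive.  Returns (scores, explained-variance ratios).
    """
    X = np.asarray(X, dtype=float)
    if n_components > X.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds {X.shape[1]} features"
        )
    Xs = StandardScaler().fit_transform(X)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[i] = -comp
            scores[:, i] = -scores[:, i]
    return scores, pca.explained_variance_ratio_


@dataclass
class AnovaResult:
    F: float
    p: float
    group_means: list[float]
    df_between: int
    df_within: int


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA, F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        F = float("inf") if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        F = float(ms_between / ms_within)
        from scipy.stats import f as f_dist

        p = float(f_dist.sf(F, df_between, df_within))
    return AnovaResult(
        F=F,
        p=p,
        group_means=[float(g.mean()) for g in groups],
        df_between=df_between,
        df_within=df_within,
    )


# ---------------------------------------------------------------------------
# method pipelines
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end settings for one method run.

    ``smote_before_split`` applies balancing to the whole dataset before
    the 60/40 split (literal protocol fidelity); the default balances the
    training split only, avoiding synthetic test rows.  ``paper_protocol``
    tunes k on the test split instead of the training split.
    """

    knn: KnnConfig = field(default_factory=KnnConfig)
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    pca_components: int = 2
    standardize: bool = True
    smote_before_split: bool = False
    paper_protocol: bool = False
    seed: int = 0

    def reseed(self, seed: int) -> "PipelineConfig":
        """Copy of the config with all sub-seeds derived from ``seed``."""
        ss = np.random.SeedSequence(seed)
        s_knn, s_boruta, s_smote = (
            int(c.generate_state(1)[0] % (2**31 - 1))
            for c in ss.spawn(3)
        )
        return replace(
            self,
            seed=seed,
            knn=replace(self.knn, seed=s_knn),
            boruta=replace(self.boruta, seed=s_boruta),
            smote=replace(self.smote, seed=s_smote),
        )


@dataclass
class MethodReport:
    method: str
    dataset_id: int | str
    confusion: Confusion
    classwise_accuracy: dict[str, float]
    classwise_recall: dict[str, float]
    average_accuracy: float
    chosen_k: int
    selected_features: list[str]
    boruta_fallback: bool = False


def run_method_on_features(
    features: pd.DataFrame,
    variant: str,
    config: PipelineConfig | None = None,
    dataset_id: int | str = 0,
) -> MethodReport:
    """Run one method variant on a precomputed feature table."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
    config = config or PipelineConfig()
    X, y = feature_matrix(features)
    if config.smote_before_split:
        X, y = smote(X, y, config.smote)
    X_tr, X_te, y_tr, y_te = split(X, y, config.knn)

    if config.standardize:
        scaler = StandardScaler().fit(X_tr)
        X_tr = scaler.transform(X_tr)
        X_te = scaler.transform(X_te)

    fallback = False
    if variant == "proposed":
        result = boruta_rank(X_tr, y_tr, config.boruta, FEATURE_NAMES)
        selected = result.confirmed
        if not selected:
            logger.warning("no confirmed features; falling back to all 19")
            selected = list(FEATURE_NAMES)
            fallback = True
        idx = [FEATURE_NAMES.index(f) for f in selected]
        X_tr, X_te = X_tr[:, idx], X_te[:, idx]
    elif variant == "pca_knn":
        pca = PCA(n_components=config.pca_components, svd_solver="full")
        X_tr = pca.fit_transform(X_tr)
        X_te = pca.transform(X_te)
        selected = [f"PC{i + 1}" for i in range(config.pca_components)]
    else:
        selected = list(FEATURE_NAMES)

    if not config.smote_before_split:
        X_tr, y_tr = smote(X_tr, y_tr, config.smote)

    cv_X, cv_y = (X_te, y_te) if config.paper_protocol else (X_tr, y_tr)
    cv = select_k(cv_X, cv_y, config.knn)
    y_pred = knn_predict(X_tr, y_tr, X_te, cv.chosen_k)
    conf = confusion_from_predictions(y_te, y_pred)
    return MethodReport(
        method=variant,
        dataset_id=dataset_id,
        confusion=conf,
        classwise_accuracy={
            "calm": classwise_accuracy(conf, CALM),
            "stress": classwise_accuracy(conf, STRESS),
        },
        classwise_recall={
            "calm": classwise_recall(conf, CALM),
            "stress": classwise_recall(conf, STRESS),
        },
        average_accuracy=average_accuracy(conf),
        chosen_k=cv.chosen_k,
        selected_features=selected,
        boruta_fallback=fallback,
    )


def run_method(
    variant: str,
    ds: ParticipantDataset,
    config: PipelineConfig | None = None,
) -> MethodReport:
    """Feature extraction plus one method variant on one participant."""
    features = extract_features(ds)
    return run_method_on_features(
        features, variant, config, dataset_id=ds.participant_id
    )


def compare_methods(
    feature_tables: dict[int | str, pd.DataFrame],
    config: PipelineConfig | None = None,
    merged: bool = True,
) -> dict:
    """All three variants per dataset, optional merged run, plus ANOVA.

    ``feature_tables`` maps dataset ids to feature DataFrames.  Returns a
    dict with per-dataset reports, the accuracy table, the ANOVA result
    across methods, and (optionally) merged-dataset reports with the
    decrement column relative to the proposed method.
    """
    config = config or PipelineConfig()
    reports: dict[str, dict] = {v: {} for v in VARIANTS}
    for ds_id, feats in feature_tables.items():
        for variant in VARIANTS:
            reports[variant][ds_id] = run_method_on_features(
                feats, variant, config, dataset_id=ds_id
            )
    accuracy = pd.DataFrame(
        {
            v: [reports[v][d].average_accuracy for d in feature_tables]
            for v in VARIANTS
        },
        index=list(feature_tables),
    )
    anova = one_way_anova([accuracy[v].to_numpy() for v in VARIANTS])
    out = {"reports": reports, "accuracy": accuracy, "anova": anova}
    if merged:
        merged_feats = pd.concat(feature_tables.values(), ignore_index=True)
        merged_reports = {
            v: run_method_on_features(merged_feats, v, config, "merged")
            for v in VARIANTS
        }
        out["merged"] = merged_reports
        out["merged_table"] = decrement_table(
            {v: r.average_accuracy for v, r in merged_reports.items()}
        )
    return out


def decrement_table(acc_by_method: dict[str, float]) -> pd.DataFrame:
    """Accuracy table with each method's decrement from the proposed one."""
    if "proposed" not in acc_by_method:
        raise ValueError("table requires a 'proposed' entry")
    ref = acc_by_method["proposed"]
    rows = [
        {
            "method": m,
            "avg_accuracy": a,
            "decrement_from_proposed": float("nan") if m == "proposed" else ref - a,
        }
        for m, a in acc_by_method.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published reference accuracies (bundled fixtures)
# ---------------------------------------------------------------------------

def load_reference_accuracies() -> pd.DataFrame:
    """Published per-dataset accuracies of the three method variants.

    25 participant-level datasets x 3 methods, as reported for the original
    study protocol on the restricted DEAP recordings; used for the
    method-comparison ANOVA.
    """
    with resources.files("eegstress.data").joinpath(
        "method_accuracy_reference.csv"
    ).open() as f:
        return pd.read_csv(f)


def load_merged_reference() -> pd.DataFrame:
    """Published merged-dataset average accuracies of the three methods."""
    with resources.files("eegstress.data").joinpath(
        "merged_accuracy_reference.csv"
    ).open() as f:
        return pd.read_csv(f)


def reference_anova() -> AnovaResult:
    """One-way ANOVA across the three published accuracy columns."""
    df = load_reference_accuracies()
    return one_way_anova(
        [df[c].to_numpy() for c in ("pca_knn", "all_features_knn", "proposed")]
    )
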