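import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegstress.evaluation import (
    CALM,
    STRESS,
    AnovaResult,
    Confusion,
    PipelineConfig,
    average_accuracy,
    classwise_accuracy,
    classwise_recall,
    confusion_from_predictions,
    decrement_table,
    load_merged_reference,
    load_reference_accuracies,
    one_way_anova,
    pca_project,
    run_method_on_features,
)
from eegstress.feature_pool import FEATURE_NAMES
from eegstress.feature_selection import BorutaConfig


class TestMetrics:
    def test_perfect_and_simple_precision(self):
        assert classwise_accuracy(Confusion(10, 0, 5, 2), STRESS) == 100.0
        assert classwise_accuracy(Confusion(3, 1, 4, 2), STRESS) == 75.0

    def test_average_accuracy_examples(self):
        assert average_accuracy(Confusion(10, 0, 5, 0)) == 100.0
        assert average_accuracy(Confusion(30, 11, 29, 10)) == 73.75

    def test_counts_match_per_row_recount(self, rng):
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        conf = confusion_from_predictions(y_true, y_pred)
        assert conf.total == 200
        # brute-force recount
        assert conf.tp == sum(
            1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1
        )
        assert average_accuracy(conf) == pytest.approx(
            100.0 * np.mean(y_true == y_pred)
        )
        for cls in (CALM, STRESS):
            mask = y_pred == cls
            assert classwise_accuracy(conf, cls) == pytest.approx(
                100.0 * np.mean(y_true[mask] == cls)
            )

    def test_label_swap_symmetry(self, rng):
        y_true = rng.integers(0, 2, 100)
        y_pred = rng.integers(0, 2, 100)
        a = confusion_from_predictions(y_true, y_pred)
        b = confusion_from_predictions(1 - y_true, 1 - y_pred)
        assert average_accuracy(a) == average_accuracy(b)
        assert classwise_accuracy(a, STRESS) == classwise_accuracy(b, CALM)

    def test_never_predicted_class_is_undefined(self):
        conf = Confusion(tp=0, fp=0, tn=5, fn=5)
        assert np.isnan(classwise_accuracy(conf, STRESS))
        assert classwise_recall(conf, STRESS) == 0.0


class TestPcaProjection:
    def test_explained_variance_matches_correlation_eigenvalues(self, rng):
        X = rng.normal(size=(300, 6)) @ rng.normal(size=(6, 6))
        scores, evr = pca_project(X, 6)
        corr = np.corrcoef(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(evr, eig / eig.sum(), rtol=1e-8, atol=1e-10)
        assert scores.shape == (300, 6)

    def test_isotropic_data_spreads_variance_evenly(self, rng):
        X = rng.normal(size=(5000, 4))
        _, evr = pca_project(X, 4)
        np.testing.assert_allclose(evr, 0.25, atol=0.03)

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(100, 5))
        s1, _ = pca_project(X, 2)
        s2, _ = pca_project(X.copy(), 2)
        np.testing.assert_allclose(s1, s2)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_project(rng.normal(size=(20, 3)), 4)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0]
        res = one_way_anova([g, g, g])
        assert res.F == 0.0
        assert res.df_between == 2 and res.df_within == 6

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        res = one_way_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t.statistic**2, abs=1e-9)
        assert res.p == pytest.approx(t.pvalue, abs=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, 20) for m in (0.0, 0.3, 1.0)]
        res = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)

    def test_zero_within_variance_marker(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.F)

    def test_reference_table_shapes(self):
        df = load_reference_accuracies()
        assert len(df) == 25
        assert {"pca_knn", "all_features_knn", "proposed"} <= set(df.columns)
        merged = load_merged_reference()
        assert len(merged) == 3


class TestDecrementTable:
    def test_decrements_relative_to_proposed(self):
        table = decrement_table(
            {"pca_knn": 60.0, "all_features_knn": 70.0, "proposed": 75.0}
        )
        by_method = table.set_index("method")["decrement_from_proposed"]
        assert by_method["pca_knn"] == pytest.approx(15.0)
        assert by_method["all_features_knn"] == pytest.approx(5.0)
        assert np.isnan(by_method["proposed"])

    def test_requires_proposed_entry(self):
        with pytest.raises(ValueError):
            decrement_table({"pca_knn": 60.0})


def noise_feature_table(n=80, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, 19)), columns=FEATURE_NAMES)
    df.insert(0, "participant_id", 1)
    df.insert(1, "experiment_id", np.arange(n) // 4 + 1)
    df.insert(2, "channel", np.arange(n) % 4)
    df["label"] = rng.permutation(np.repeat([0, 1], n // 2))
    return df


class TestMethodPipeline:
    def test_no_confirmed_features_falls_back_with_flag(self):
        df = noise_feature_table(seed=3)
        cfg = PipelineConfig(
            boruta=BorutaConfig(n_iterations=5, rf_trees=30, seed=1)
        )
        report = run_method_on_features(df, "proposed", cfg)
        assert report.boruta_fallback
        assert report.selected_features == FEATURE_NAMES
        assert report.confusion.total == len(df) * 2 // 5  # 40% test split

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            run_method_on_features(noise_feature_table(), "nope")

    def test_report_is_reproducible_under_fixed_seed(self):
        df = noise_feature_table(seed=4)
        cfg = PipelineConfig(
            boruta=BorutaConfig(n_iterations=3, rf_trees=20, seed=0)
        ).reseed(99)
        r1 = run_method_on_features(df, "all_features_knn", cfg)
        r2 = run_method_on_features(df, "all_features_knn", cfg)
        assert r1.confusion == r2.confusion
        assert r1.chosen_k == r2.chosen_k
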