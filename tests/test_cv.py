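"""Metrics, fold plans, adapters, correlation and the CV pipeline."""

import numpy as np
import pytest
from scipy import stats

from oilblend import (
    PipelineConfig,
    ScatterNoiseModel,
    accuracy,
    assign_class_labels,
    fit_classifier,
    fit_regressor,
    generate_dataset,
    make_folds,
    pcc_by_wavelength,
    r2_rmse,
    run_cv_pipeline,
)
from oilblend.exceptions import ConfigError, ParameterError


class TestMetrics:
    def test_accuracy_hand_cases(self):
        assert accuracy(["a", "b", "c"], ["a", "b", "c"]) == 1.0
        assert accuracy(["a", "b", "c", "d"], ["a", "b", "c", "x"]) == 0.75
        assert accuracy(["a", "b"], ["x", "y"]) == 0.0

    def test_accuracy_empty_rejected(self):
        with pytest.raises(ParameterError):
            accuracy([], [])

    def test_r2_rmse_hand_case(self):
        r2, rmse = r2_rmse([0, 0.5, 1], [0.1, 0.5, 0.9])
        assert r2 == pytest.approx(0.96, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(0.02 / 3), abs=1e-12)

    def test_r2_limits(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2_rmse(y, y) == (1.0, 0.0)
        r2, _ = r2_rmse(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_truth_rejected(self):
        with pytest.raises(ParameterError):
            r2_rmse([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])


class TestFoldPlan:
    def test_110_samples_make_ten_folds_of_eleven(self):
        plan = make_folds(110, folds=10, seed=0)
        sizes = np.bincount(plan.assignment, minlength=10)
        assert sizes.tolist() == [11] * 10

    def test_partition_is_disjoint_and_exhaustive(self):
        plan = make_folds(47, folds=10, seed=1)
        seen = np.zeros(47, dtype=int)
        for cal, pred in plan.split():
            assert np.intersect1d(cal, pred).size == 0
            seen[pred] += 1
        assert np.all(seen == 1)
        sizes = np.bincount(plan.assignment)
        assert sizes.max() - sizes.min() <= 1

    def test_same_seed_identical_assignment(self):
        a = make_folds(60, 10, seed=9)
        b = make_folds(60, 10, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_stratification_spreads_each_stratum(self):
        strata = np.repeat(np.arange(5), 20)  # 5 strata of 20
        plan = make_folds(100, folds=10, seed=2, stratify_by=strata)
        for s in range(5):
            folds_hit = np.bincount(plan.assignment[strata == s], minlength=10)
            assert folds_hit.max() - folds_hit.min() <= 1

    def test_more_folds_than_samples_rejected(self):
        with pytest.raises(ParameterError):
            make_folds(5, folds=6)


class TestAdapters:
    def test_knn_k1_memorises_training_data(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = rng.integers(0, 3, 30).astype(str)
        est = fit_classifier("knn", X, y, hyperparams={"n_neighbors": 1})
        assert accuracy(y, est.predict(X)) == 1.0

    def test_svm_separates_linearly_separable_classes(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.3, (20, 4)), rng.normal(3, 0.3, (20, 4))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        est = fit_classifier("svm", X, y)
        assert accuracy(y, est.predict(X)) == 1.0

    def test_rf_regression_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        y = X[:, 0] + 0.1 * rng.standard_normal(40)
        p1 = fit_regressor("rf", X, y, hyperparams={"n_estimators": 50},
                           seed=7).predict(X)
        p2 = fit_regressor("rf", X, y, hyperparams={"n_estimators": 50},
                           seed=7).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            fit_regressor("gbm", np.ones((4, 2)), np.ones(4))


class TestPCC:
    def test_exactly_linear_reflectance_gives_unit_correlation(self, tiny_set):
        ratios = tiny_set.ratios()
        tiny_set.reflectance = np.column_stack([
            0.2 + 0.5 * ratios,       # positive slope
            0.9 - 0.4 * ratios,       # negative slope
            0.1 + 0.0 * ratios + [0.01, 0.02, 0.03],  # incidental
        ])
        from oilblend.spectra import WavelengthGrid
        tiny_set.grid = WavelengthGrid(np.array([400.0, 500.0, 600.0]))
        r, p = pcc_by_wavelength(tiny_set)
        assert r[0] == pytest.approx(1.0, abs=1e-12)
        assert r[1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_scipy_pearsonr_oracle(self, default_dataset):
        small = default_dataset.subset(range(0, 110, 5))
        r, p = pcc_by_wavelength(small)
        for j in (0, 500, 1000, 2000):
            expect = stats.pearsonr(small.reflectance[:, j], small.ratios())
            assert r[j] == pytest.approx(expect.statistic, abs=1e-12)
            assert p[j] == pytest.approx(expect.pvalue, rel=1e-9)

    def test_visible_band_correlates_negatively_with_genuine_ratio(
            self, default_dataset):
        """Soybean oil is the brightest in the visible band, so reflectance
        there falls as the genuine-oil fraction rises."""
        rows = [i for i, m in enumerate(default_dataset.meta)
                if m.case == "sesame_soy"]
        sub = default_dataset.subset(rows)
        r, p = pcc_by_wavelength(sub)
        j546 = int(np.argmin(np.abs(sub.grid.values - 546)))
        assert r[j546] < -0.5 and p[j546] < 1e-4

    def test_too_few_samples_rejected(self, tiny_set):
        with pytest.raises(ParameterError):
            pcc_by_wavelength(tiny_set.subset([0, 1]))


class TestPipeline:
    def test_noiseless_regression_is_essentially_exact(self, noiseless_dataset):
        cfg = PipelineConfig(task="regress_rate", case="sesame_soy",
                             pretreatment="raw", model="plsr", seed=0)
        res = run_cv_pipeline(noiseless_dataset, cfg)
        assert res.aggregates["r2_p"] > 0.9999
        assert res.aggregates["rmse_p"] < 1e-6

    def test_aggregates_equal_mean_of_folds(self, noiseless_dataset):
        cfg = PipelineConfig(task="regress_rate", case="rapeseed_soy",
                             pretreatment="snv", model="plsr", seed=1)
        res = run_cv_pipeline(noiseless_dataset, cfg)
        for key, agg in res.aggregates.items():
            assert agg == pytest.approx(
                np.mean([f[key] for f in res.per_fold]), abs=1e-12)

    def test_every_sample_predicted_exactly_once(self, noiseless_dataset):
        cfg = PipelineConfig(task="regress_rate", case="sesame_soy",
                             model="plsr", seed=3)
        rows = [i for i, m in enumerate(noiseless_dataset.meta)
                if m.case == "sesame_soy"]
        plan = make_folds(len(rows), folds=10, seed=3)
        counts = np.zeros(len(rows), int)
        for _, pred in plan.split():
            counts[pred] += 1
        assert np.all(counts == 1)

    def test_classification_excludes_half_blends_and_has_seven_classes(
            self, default_dataset):
        labelled = assign_class_labels(default_dataset)
        cfg = PipelineConfig(task="classify_type", pretreatment="snv",
                             model="knn", seed=0)
        res = run_cv_pipeline(labelled, cfg)
        assert len(res.per_fold) == 10
        kept = [m for m in labelled.meta if abs(m.genuine_ratio - 0.5) > 1e-9]
        assert len(kept) == 100
        assert len({m.class_label for m in kept}) == 7

    def test_pooled_mode_records_provenance(self, noiseless_dataset):
        cfg = PipelineConfig(task="regress_rate", case="sesame_soy",
                             pretreatment="msc", model="plsr",
                             leakage_mode="pooled", seed=0)
        res = run_cv_pipeline(noiseless_dataset, cfg)
        assert res.config["leakage_mode"] == "pooled"
        assert res.aggregates["r2_p"] > 0.999

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            PipelineConfig(task="cluster")
        with pytest.raises(ConfigError):
            PipelineConfig(leakage_mode="loose")
        with pytest.raises(ConfigError):
            PipelineConfig(selection="uve")
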