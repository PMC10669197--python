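import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vesselage import modeling as MD
from vesselage.cohort import FEATURE_COLUMNS
from vesselage.phantom import CohortSpec, simulate_tabular_cohort


class TestEvaluate:
    def test_perfect_predictions(self):
        x = np.array([30.0, 45.0, 60.0, 75.0])
        m = MD.evaluate(x, x)
        assert m.r == pytest.approx(1.0)
        assert m.rmse == 0.0
        assert m.mape == 0.0
        assert m.r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        m = MD.evaluate(np.array([50.0, 60.0]), np.array([55.0, 54.0]))
        assert m.rmse == pytest.approx(np.sqrt((25.0 + 36.0) / 2.0))
        assert m.mape == pytest.approx(0.1)

    def test_mean_predictor_gives_zero_r2(self):
        x = np.array([20.0, 40.0, 60.0, 80.0])
        m = MD.evaluate(x, np.full(4, x.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_r_undefined_others_fine(self):
        x = np.array([30.0, 50.0, 70.0])
        m = MD.evaluate(x, np.array([50.0, 50.0, 50.0]))
        assert np.isnan(m.r)
        assert m.notes
        assert np.isfinite(m.rmse) and np.isfinite(m.mape) and np.isfinite(m.r2)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            MD.evaluate(np.array([0.0, 50.0]), np.array([10.0, 50.0]))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            MD.evaluate(np.array([1.0, 2.0]), np.array([1.0]))

    @given(
        hnp.arrays(np.float64, st.integers(3, 40),
                   elements=st.floats(min_value=1.0, max_value=100.0)),
        st.integers(0, 2**32 - 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_r2_rmse_identity(self, x, seed):
        rng = np.random.default_rng(seed)
        y = x + rng.normal(0.0, 5.0, size=len(x))
        sxx = np.sum((x - x.mean()) ** 2)
        if sxx == 0.0:
            return
        m = MD.evaluate(x, y)
        # abs tolerance for ordinary scales, rel for near-constant x where
        # R^2 blows up to huge magnitudes
        assert m.r2 == pytest.approx(1.0 - (m.rmse**2 * len(x)) / sxx, rel=1e-9, abs=1e-12)

    def test_r_invariant_under_positive_affine_y(self, rng):
        x = rng.uniform(20.0, 80.0, size=25)
        y = x + rng.normal(0.0, 8.0, size=25)
        r0 = MD.evaluate(x, y).r
        r1 = MD.evaluate(x, 3.5 * y + 11.0).r
        assert r1 == pytest.approx(r0, rel=1e-12)


class TestAssignFolds:
    def test_171_subjects_4_folds(self):
        labels = MD.assign_folds([f"s{i}" for i in range(171)], 4, seed=0)
        sizes = sorted(np.bincount(labels).tolist())
        assert sizes == [42, 43, 43, 43]

    def test_8_subjects_4_folds_all_pairs(self):
        labels = MD.assign_folds(list(range(8)), 4, seed=1)
        assert np.bincount(labels).tolist() == [2, 2, 2, 2]

    def test_reproducible(self):
        a = MD.assign_folds(list(range(50)), 4, seed=7)
        b = MD.assign_folds(list(range(50)), 4, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            MD.assign_folds([1, 2, 3], 4)


class TestModelSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            MD.ModelSpec(family="svm")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            MD.ModelSpec(family="random_forest", params={"nope": 1})

    def test_registry_defaults(self):
        spec = MD.ModelSpec(family="random_forest")
        p = spec.resolved_params()
        assert p["n_estimators"] == 74
        assert p["max_depth"] == 14
        assert p["min_samples_leaf"] == 2
        assert p["min_samples_split"] == 6
        assert p["max_features"] == "sqrt"
        assert p["criterion"] == "absolute_error"

    def test_build_estimator_families(self):
        from sklearn.ensemble import (AdaBoostRegressor, GradientBoostingRegressor,
                                      RandomForestRegressor)
        from sklearn.linear_model import BayesianRidge, LinearRegression

        expected = {
            "random_forest": RandomForestRegressor,
            "linear": LinearRegression,
            "adaboost": AdaBoostRegressor,
            "gradient_boosting": GradientBoostingRegressor,
            "bayesian_ridge": BayesianRidge,
            "xgb_style_boosting": GradientBoostingRegressor,
        }
        for family, cls in expected.items():
            assert isinstance(MD.build_estimator(MD.ModelSpec(family=family)), cls)

    def test_xgb_style_controls_mapped(self):
        est = MD.build_estimator(MD.ModelSpec(family="xgb_style_boosting"))
        assert est.max_features == 0.95       # colsample_bytree
        assert est.min_impurity_decrease == 0.22  # gamma
        assert est.subsample == 0.84
        assert est.learning_rate == 0.30
        assert est.max_depth == 4
        assert est.n_estimators == 138

    def test_adaboost_table_values(self):
        est = MD.build_estimator(MD.ModelSpec(family="adaboost"))
        assert est.learning_rate == 0.07
        assert est.loss == "exponential"
        assert est.n_estimators == 163

    def test_bayesian_ridge_table_values(self):
        est = MD.build_estimator(MD.ModelSpec(family="bayesian_ridge"))
        assert est.alpha_1 == 0.0004
        assert est.alpha_2 == 1e-6
        assert est.alpha_init == 10.0
        assert est.lambda_1 == 1e-5
        assert est.tol == 0.01


class TestRandomizedSearch:
    def _data(self, rng, n=60):
        X = rng.normal(size=(n, 5))
        y = 50.0 + 3.0 * X[:, 0] + rng.normal(0.0, 1.0, size=n)
        return X, y

    def test_empty_space_returns_spec_with_warning(self, rng):
        X, y = self._data(rng)
        spec = MD.ModelSpec(family="linear")
        res = MD.randomized_search(spec, X, y, n_iter=5, seed=0)
        assert res.spec == spec
        assert res.warnings

    def test_single_point_space(self, rng):
        X, y = self._data(rng)
        spec = MD.ModelSpec(family="random_forest",
                            search_space={"n_estimators": [10]},
                            params={"criterion": "squared_error"})
        res = MD.randomized_search(spec, X, y, n_iter=3, seed=0)
        assert res.spec.params["n_estimators"] == 10

    def test_n_iter_one_returns_sampled_config(self, rng):
        X, y = self._data(rng)
        spec = MD.ModelSpec(family="random_forest",
                            search_space={"n_estimators": [5, 10, 20]},
                            params={"criterion": "squared_error"})
        res = MD.randomized_search(spec, X, y, n_iter=1, seed=3)
        assert res.spec.params["n_estimators"] in (5, 10, 20)
        again = MD.randomized_search(spec, X, y, n_iter=1, seed=3)
        assert again.spec.params == res.spec.params


def small_specs(seed=0):
    """Cheap specs for structural run_cv tests."""
    overrides = {
        "random_forest": {"criterion": "squared_error", "n_estimators": 20},
        "gradient_boosting": {"n_estimators": 30, "max_depth": 3},
        "adaboost": {"n_estimators": 20},
        "xgb_style_boosting": {"n_estimators": 30},
    }
    return [MD.ModelSpec(family=f, params=overrides.get(f, {}), seed=seed)
            for f in MD.FAMILIES]


class TestRunCV:
    def test_noiseless_linear_cohort_exact_recovery(self):
        spec = CohortSpec(n_subjects=64,
                          coefficients={"R-ICA_diam_mean": 10.0, "BA_lc": 0.4},
                          intercept=8.0, noise_sd=0.0, seed=2)
        table = simulate_tabular_cohort(spec)
        result = MD.run_cv(table, [MD.ModelSpec(family="linear")], k=4, seed=0)
        res = result.per_model["linear"]
        assert res.errors == []
        assert res.mean["rmse"] < 1e-6
        assert res.mean["r"] == pytest.approx(1.0, abs=1e-9)

    def test_validation_rmse_approaches_noise_sd(self):
        spec = CohortSpec(n_subjects=2000, coefficients={"R-ICA_diam_mean": 10.0},
                          intercept=15.0, noise_sd=6.0, seed=4)
        table = simulate_tabular_cohort(spec)
        result = MD.run_cv(table, [MD.ModelSpec(family="linear")], k=4, seed=0)
        assert result.per_model["linear"].mean["rmse"] == pytest.approx(6.0, rel=0.10)

    def test_six_families_produce_six_rows(self):
        table = simulate_tabular_cohort(
            CohortSpec(n_subjects=24, coefficients={"BA_diam_mean": 8.0}, noise_sd=3.0, seed=1)
        )
        result = MD.run_cv(table, small_specs(), k=4, seed=0)
        assert set(result.per_model) == set(MD.FAMILIES)
        frame = MD.metrics_frame(result)
        assert len(frame) == 6
        for res in result.per_model.values():
            assert res.errors == []
            assert len(res.fold_metrics) == 4

    def test_folds_partition_and_each_subject_predicted_once(self):
        table = simulate_tabular_cohort(CohortSpec(n_subjects=21, noise_sd=2.0, seed=6))
        result = MD.run_cv(table, [MD.ModelSpec(family="linear")], k=4, seed=0)
        preds = result.per_model["linear"].predictions
        assert sorted(preds["subject_id"]) == sorted(table["subject_id"])
        sizes = sorted(np.bincount(result.fold_labels).tolist())
        assert max(sizes) - min(sizes) <= 1

    def test_importances_present_for_tree_families_sum_to_one(self):
        table = simulate_tabular_cohort(
            CohortSpec(n_subjects=24, coefficients={"BA_diam_mean": 8.0}, noise_sd=2.0, seed=9)
        )
        result = MD.run_cv(table, small_specs(), k=4, seed=0)
        for family, res in result.per_model.items():
            if family in MD.TREE_FAMILIES:
                weights = [w for _, w in res.importances]
                assert sum(weights) == pytest.approx(1.0, abs=1e-9)
                assert all(weights[i] >= weights[i + 1] for i in range(len(weights) - 1))
            else:
                assert res.importances is None

    def test_deterministic_under_seed(self):
        table = simulate_tabular_cohort(CohortSpec(n_subjects=20, noise_sd=2.0, seed=3))
        specs = [MD.ModelSpec(family="random_forest",
                              params={"criterion": "squared_error", "n_estimators": 15}, seed=5)]
        r1 = MD.run_cv(table, specs, k=4, seed=11)
        r2 = MD.run_cv(table, specs, k=4, seed=11)
        p1 = r1.per_model["random_forest"].predictions["predicted"].to_numpy()
        p2 = r2.per_model["random_forest"].predictions["predicted"].to_numpy()
        np.testing.assert_array_equal(p1, p2)

    def test_leakage_guard_shuffled_ages(self):
        # with the age-feature link broken, validation r stays near zero
        rs = []
        for seed in range(20):
            table = simulate_tabular_cohort(
                CohortSpec(n_subjects=100, coefficients={"BA_diam_mean": 8.0},
                           noise_sd=2.0, seed=seed)
            )
            rng = np.random.default_rng(seed)
            table = table.assign(age=rng.permutation(table["age"].to_numpy()))
            result = MD.run_cv(table, [MD.ModelSpec(family="linear")], k=4, seed=seed)
            rs.append(result.per_model["linear"].mean["r"])
        assert abs(np.mean(rs)) < 2.0 / np.sqrt(100)


class TestFeatureImportance:
    def test_single_causal_feature_ranks_first(self):
        table = simulate_tabular_cohort(
            CohortSpec(n_subjects=120, coefficients={"R-ICA_diam_mean": 15.0},
                       noise_sd=2.0, seed=13)
        )
        result = MD.run_cv(table, [MD.ModelSpec(family="random_forest", seed=13)], k=4, seed=13)
        assert result.per_model["random_forest"].importances[0][0] == "R-ICA_diam_mean"

    def test_duplicated_causal_feature_shares_importance(self, rng):
        from sklearn.ensemble import RandomForestRegressor

        n = 300
        causal = rng.normal(0.0, 1.0, size=n)
        noise_cols = rng.normal(size=(n, 4))
        y = 50.0 + 10.0 * causal + rng.normal(0.0, 1.0, size=n)

        X_single = np.column_stack([causal, noise_cols])
        X_dup = np.column_stack([causal, causal, noise_cols])
        imp_single = MD.feature_importance(
            RandomForestRegressor(n_estimators=100, random_state=0).fit(X_single, y),
            ["c", "n1", "n2", "n3", "n4"],
        )
        imp_dup = MD.feature_importance(
            RandomForestRegressor(n_estimators=100, random_state=0).fit(X_dup, y),
            ["c1", "c2", "n1", "n2", "n3", "n4"],
        )
        total_single = dict(imp_single)["c"]
        total_dup = dict(imp_dup)["c1"] + dict(imp_dup)["c2"]
        assert total_dup == pytest.approx(total_single, abs=0.1)

    def test_non_tree_model_rejected(self):
        from sklearn.linear_model import LinearRegression

        model = LinearRegression().fit(np.eye(3), np.arange(3.0))
        with pytest.raises(ValueError, match="tree"):
            MD.feature_importance(model, ["a", "b", "c"])

    def test_name_length_mismatch_rejected(self):
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(n_estimators=5, random_state=0).fit(
            np.random.default_rng(0).normal(size=(20, 3)), np.arange(20.0)
        )
        with pytest.raises(ValueError, match="count"):
            MD.feature_importance(model, ["a", "b"])


class TestScatterPlot:
    def test_file_and_sidecar_written(self, tmp_path, rng):
        x = rng.uniform(20, 80, size=30)
        y = x + rng.normal(0, 5, size=30)
        dest = tmp_path / "scatter.png"
        MD.scatter_plot(x, y, dest)
        assert dest.exists() and dest.stat().st_size > 0
        side = json.loads((tmp_path / "scatter.png.json").read_text())
        np.testing.assert_allclose(side["real"], x)
        np.testing.assert_allclose(side["predicted"], y)

    def test_perfect_predictions_lie_on_identity(self, tmp_path):
        x = np.linspace(20, 80, 10)
        dest = tmp_path / "p.png"
        MD.scatter_plot(x, x, dest)
        side = json.loads((tmp_path / "p.png.json").read_text())
        np.testing.assert_allclose(side["real"], side["predicted"])

    def test_empty_pair_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            MD.scatter_plot(np.array([]), np.array([]), tmp_path / "e.png")
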