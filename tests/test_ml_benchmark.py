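import itertools

import numpy as np
import pytest

from broilerweight import ml_benchmark as mb
from broilerweight.synthetic_data import BirdRecord, CohortConfig, generate_cohort

SMALL_GRIDS = {
    "rf": {"n_estimators": [50], "max_depth": [5, None]},
    "gbt": {"n_estimators": [50], "max_depth": [3]},
    "svr": {"C": [1000.0], "epsilon": [0.01]},
    "knn": {"n_neighbors": [5, 11]},
    "mlr": {},
}


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(n_birds=12, seed=13))


@pytest.fixture(scope="module")
def report(cohort):
    cfg = mb.BenchmarkConfig(
        dataset="mixed", n_repeats=3, cv_folds=3, grids=SMALL_GRIDS, seed=42,
        shapley_instances=5, shapley_background=20,
    )
    return mb.tune_and_evaluate(cohort, cfg)


class TestMinMaxScale:
    def test_midpoint(self):
        scaled, flags, _ = mb.minmax_scale(np.array([[0.0], [10.0]]), np.array([[5.0]]))
        assert scaled[0, 0] == pytest.approx(0.5)
        assert not flags[0]

    def test_endpoints(self):
        scaled, _, _ = mb.minmax_scale(np.array([[0.0], [10.0]]), np.array([[0.0], [10.0]]))
        assert scaled[0, 0] == 0.0 and scaled[1, 0] == 1.0

    def test_out_of_range_flagged(self):
        scaled, flags, _ = mb.minmax_scale(np.array([[0.0], [10.0]]), np.array([[12.0]]))
        assert scaled[0, 0] == pytest.approx(1.2)
        assert flags[0]

    def test_constant_feature_raises(self):
        with pytest.raises(ValueError, match="constant"):
            mb.minmax_scale(np.array([[3.0], [3.0]]), np.array([[3.0]]))

    def test_scaler_fitted_on_train_only(self):
        train = np.array([[0.0, 0.0], [10.0, 100.0]])
        _, _, scaler = mb.minmax_scale(train, train)
        out = scaler.transform(np.array([[20.0, 50.0]]))
        assert out[0, 0] == pytest.approx(2.0)
        assert out[0, 1] == pytest.approx(0.5)


class TestSplitRecords:
    def test_4200_gives_3360_840(self, default_cohort):
        train, test = mb.split_records(default_cohort, 0.2, seed=0)
        assert len(train) == 3360 and len(test) == 840

    def test_same_seed_identical(self, cohort):
        a = mb.split_records(cohort, 0.2, seed=5)
        b = mb.split_records(cohort, 0.2, seed=5)
        assert a == b

    def test_union_is_input_multiset(self, cohort):
        train, test = mb.split_records(cohort, 0.2, seed=1)
        key = lambda r: (r.bird_id, r.day)
        assert sorted(map(key, train + test)) == sorted(map(key, cohort))

    def test_disjoint(self, cohort):
        train, test = mb.split_records(cohort, 0.2, seed=2)
        assert not ({(r.bird_id, r.day) for r in train} & {(r.bird_id, r.day) for r in test})

    def test_stratified_covers_all_bands(self, cohort):
        _, test = mb.split_records(cohort, 0.2, seed=3)
        bands = {(r.day - 1) // 7 for r in test}
        assert bands == set(range(6))

    def test_too_few_records_raises(self, cohort):
        with pytest.raises(ValueError):
            mb.split_records(cohort[:1], 0.2, seed=0)


class TestTuneAndEvaluate:
    def test_report_cardinality(self, report):
        assert len(report.results) == 5 * 3

    def test_test_metrics_finite_and_reasonable(self, report):
        assert np.isfinite(report.results["rmse_test_g"]).all()
        assert (report.results["r2_test"] > 0.5).all()

    def test_perfectly_linear_data_mlr_exact(self, rng):
        records = []
        for i in range(300):
            length = float(rng.uniform(50, 200))
            width = float(rng.uniform(40, 150))
            lw = 3.0 * length + 5.0 * width
            records.append(
                BirdRecord(
                    bird_id=f"b{i // 42}", sex="male", day=i % 42 + 1,
                    back_length=length, back_width=width, live_weight=lw,
                )
            )
        cfg = mb.BenchmarkConfig(
            dataset="male", n_repeats=1, cv_folds=2,
            grids={"mlr": {}}, algorithms=("mlr",), seed=0, shapley_instances=0,
        )
        rep = mb.tune_and_evaluate(records, cfg)
        row = rep.results.iloc[0]
        assert row["r2_test"] == pytest.approx(1.0, abs=1e-10)
        assert row["rmse_test_g"] == pytest.approx(0.0, abs=1e-6)

    def test_nonlinear_models_beat_mlr_on_allometric_data(self, cohort):
        cfg = mb.BenchmarkConfig(
            dataset="mixed", n_repeats=10, cv_folds=3, grids=SMALL_GRIDS, seed=3,
            shapley_instances=0,
        )
        rep = mb.tune_and_evaluate(cohort, cfg)
        wins = 0
        for r in range(10):
            sub = rep.results[rep.results["repeat"] == r].set_index("algorithm")
            mlr = sub.loc["mlr", "rmse_test_g"]
            if all(sub.loc[a, "rmse_test_g"] <= mlr for a in ("rf", "gbt", "svr", "knn")):
                wins += 1
        assert wins >= 8

    def test_repeats_use_different_partitions(self, cohort):
        cfg = mb.BenchmarkConfig(
            dataset="mixed", n_repeats=3, cv_folds=3,
            grids={"mlr": {}}, algorithms=("mlr",), seed=1, shapley_instances=0,
        )
        partitions = [
            {(r.bird_id, r.day) for r in mb.split_records(cohort, 0.2, seed=cfg.seed + 1000 * i)[1]}
            for i in range(3)
        ]
        assert not (partitions[0] == partitions[1] == partitions[2])

    def test_dataset_filter(self, cohort):
        cfg = mb.BenchmarkConfig(
            dataset="female", n_repeats=1, cv_folds=2,
            grids={"mlr": {}}, algorithms=("mlr",), seed=0, shapley_instances=0,
        )
        rep = mb.tune_and_evaluate(cohort, cfg)
        assert rep.results.iloc[0]["dataset"] == "female"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            mb.BenchmarkConfig(test_fraction=0.0).validate()
        with pytest.raises(ValueError):
            mb.BenchmarkConfig(n_repeats=0).validate()
        with pytest.raises(ValueError):
            mb.BenchmarkConfig(dataset="other").validate()


def _brute_force_shapley(predict_fn, instance, background):
    """Independent oracle: average marginal contribution over all
    feature-permutation orderings, marginalizing absent features over
    the background set."""
    n_feat = len(instance)
    phis = np.zeros(n_feat)

    def value(coalition):
        X = background.copy()
        for j in coalition:
            X[:, j] = instance[j]
        return float(np.mean(predict_fn(X)))

    perms = list(itertools.permutations(range(n_feat)))
    for perm in perms:
        seen = []
        for j in perm:
            before = value(tuple(seen))
            seen.append(j)
            phis[j] += value(tuple(seen)) - before
    return phis / len(perms)


class TestShapley:
    def test_product_model_symmetric_singleton_background(self):
        f = lambda X: X[:, 0] * X[:, 1]
        phi0, phi1, base = mb.shapley_two_feature(f, np.array([2.0, 3.0]), np.array([[0.0, 0.0]]))
        assert phi0 == pytest.approx(3.0)
        assert phi1 == pytest.approx(3.0)
        assert base == pytest.approx(0.0)

    def test_additive_model_phi_independent_of_other_feature(self, rng):
        f = lambda X: np.sin(X[:, 0]) + X[:, 1] ** 2
        bg = rng.normal(size=(30, 2))
        x1 = np.array([0.7, 1.0])
        x2 = np.array([0.7, -2.0])
        phi_a, _, _ = mb.shapley_two_feature(f, x1, bg)
        phi_b, _, _ = mb.shapley_two_feature(f, x2, bg)
        assert phi_a == pytest.approx(phi_b, abs=1e-12)

    def test_local_accuracy_identity(self, rng):
        f = lambda X: X[:, 0] ** 2 + 3 * X[:, 0] * X[:, 1] - X[:, 1]
        for _ in range(10):
            x = rng.normal(size=2)
            bg = rng.normal(size=(20, 2))
            phi0, phi1, base = mb.shapley_two_feature(f, x, bg)
            assert phi0 + phi1 + base == pytest.approx(float(f(x[None, :])[0]), abs=1e-10)

    def test_matches_brute_force_enumeration(self, rng):
        f = lambda X: np.exp(0.1 * X[:, 0]) * (1 + X[:, 1] ** 2)
        for _ in range(5):
            x = rng.normal(size=2)
            bg = rng.normal(size=(15, 2))
            phi0, phi1, _ = mb.shapley_two_feature(f, x, bg)
            brute = _brute_force_shapley(f, x, bg)
            assert phi0 == pytest.approx(brute[0], abs=1e-12)
            assert phi1 == pytest.approx(brute[1], abs=1e-12)

    def test_wrong_feature_count_raises(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError, match="two features"):
            mb.shapley_two_feature(f, np.array([1.0, 2.0, 3.0]), np.ones((5, 3)))

    def test_empty_background_raises(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError, match="background"):
            mb.shapley_two_feature(f, np.array([1.0, 2.0]), np.empty((0, 2)))

    def test_width_dominates_when_width_carries_signal(self, rng):
        # synthetic construction where width carries far more signal
        from sklearn.ensemble import RandomForestRegressor

        X = rng.uniform(0, 1, size=(400, 2))
        y = 50 * X[:, 1] ** 2 + 2 * X[:, 0] + rng.normal(0, 0.5, 400)
        model = RandomForestRegressor(n_estimators=50, random_state=0).fit(X, y)
        bg = X[:50]
        phis = np.array(
            [mb.shapley_two_feature(model.predict, X[i], bg)[:2] for i in range(50, 80)]
        )
        mean_abs = np.abs(phis).mean(axis=0)
        assert mean_abs[1] > mean_abs[0]


class TestShapleyInReport:
    def test_shapley_rows_present(self, report):
        assert set(report.shapley["algorithm"]) == {"rf", "gbt", "svr", "knn", "mlr"}
        assert (report.shapley[["mean_abs_shap_length", "mean_abs_shap_width"]] >= 0).all().all()

    def test_summary_shape(self, report):
        s = report.summary()
        assert len(s) == 5
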