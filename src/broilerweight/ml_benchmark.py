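"""Benchmarking harness for morphometric live-weight regressors.

Protocol: min-max scaling fitted on the training subset only, a
record-level 80/20 split stratified by 7-day age band, grid search with
k-fold cross-validation on a 90% tuning subset of the training data, the
winning configuration retrained on the full training set, and the whole
procedure repeated over fresh random splits. Learners come from
scikit-learn; this module owns the protocol, not the models.

Gradient-boosted trees (``gbt``) stand in for an extreme-gradient-
boosting implementation; the hyperparameter grid is equivalent
(learning_rate, max_depth, n_estimators, subsample).

Also provides exact two-feature Shapley attribution with a background
set (interventional form), closed over both feature orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from broilerweight import metrics
from broilerweight.pixel_regression import WEEK_BANDS
from broilerweight.synthetic_data import BirdRecord

__all__ = [
    "BenchmarkConfig",
    "EvaluationReport",
    "MinMaxScaler2",
    "minmax_scale",
    "split_records",
    "tune_and_evaluate",
    "shapley_two_feature",
    "DEFAULT_GRIDS",
    "ALGORITHMS",
]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {
        "n_estimators": [100, 150],
        "max_depth": [3, 5],
        "min_samples_split": [2, 5],
        "min_samples_leaf": [1, 2],
    },
    "gbt": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [3],
        "n_estimators": [100, 200],
        "subsample": [0.8, 1.0],
    },
    "svr": {"C": [100.0, 1000.0], "epsilon": [0.01, 0.5], "kernel": ["rbf"]},
    "knn": {"n_neighbors": [5, 11, 13], "p": [1, 2], "weights": ["uniform"]},
    "mlr": {},
}


def _make_estimator(name: str, seed: int):
    if name == "rf":
        return RandomForestRegressor(random_state=seed)
    if name == "gbt":
        return GradientBoostingRegressor(random_state=seed)
    if name == "svr":
        return SVR()
    if name == "knn":
        return KNeighborsRegressor()
    if name == "mlr":
        return LinearRegression()
    raise KeyError(f"unknown algorithm {name!r}")


ALGORITHMS = ("rf", "gbt", "svr", "knn", "mlr")


@dataclass
class BenchmarkConfig:
    dataset: str = "mixed"  # male | female | mixed
    test_fraction: float = 0.2
    tuning_fraction_of_train: float = 0.9
    n_repeats: int = 10
    cv_folds: int = 5
    grids: dict[str, dict[str, list]] = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    algorithms: tuple[str, ...] = ALGORITHMS
    seed: int = 0
    stratify_by_band: bool = True
    shapley_instances: int = 20
    shapley_background: int = 50

    def validate(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if not 0 < self.tuning_fraction_of_train <= 1:
            raise ValueError("tuning_fraction_of_train must lie in (0, 1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.dataset not in ("male", "female", "mixed"):
            raise ValueError("dataset must be male, female or mixed")


@dataclass
class EvaluationReport:
    results: pd.DataFrame  # one row per algorithm x repeat
    shapley: pd.DataFrame  # mean |phi| per algorithm x feature
    config: BenchmarkConfig

    def summary(self) -> pd.DataFrame:
        cols = ["r2_train", "rmse_train_g", "mape_train_pct", "r2_test", "rmse_test_g", "mape_test_pct"]
        return self.results.groupby("algorithm")[cols].agg(["mean", "std"])


class MinMaxScaler2:
    """Min-max scaler fitted on training data only.

    Applied values may fall outside [0, 1] (e.g. test extremes); callers
    can detect this via ``out_of_range``.
    """

    def __init__(self) -> None:
        self.min_: Optional[np.ndarray] = None
        self.range_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler2":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.range_ = X.max(axis=0) - self.min_
        if np.any(self.range_ == 0):
            bad = np.where(self.range_ == 0)[0].tolist()
            raise ValueError(f"constant feature(s) at column(s) {bad}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, dtype=float) - self.min_) / self.range_

    @staticmethod
    def out_of_range(scaled: np.ndarray) -> np.ndarray:
        return np.any((scaled < 0) | (scaled > 1), axis=-1)


def minmax_scale(
    train: np.ndarray, apply_to: np.ndarray
) -> tuple[np.ndarray, np.ndarray, MinMaxScaler2]:
    """Scale ``apply_to`` with a scaler fitted on ``train`` only.

    Returns (scaled values, out-of-range flags, fitted scaler).
    """
    scaler = MinMaxScaler2().fit(np.atleast_2d(np.asarray(train, dtype=float).T).T)
    arr = np.atleast_2d(np.asarray(apply_to, dtype=float).T).T
    scaled = scaler.transform(arr)
    return scaled, scaler.out_of_range(scaled), scaler


def _band_index(day: int) -> int:
    for i, (lo, hi) in enumerate(WEEK_BANDS):
        if lo <= day <= hi:
            return i
    return len(WEEK_BANDS)  # days beyond the canonical range pool together


def split_records(
    records: Sequence[BirdRecord],
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify_by_band: bool = True,
) -> tuple[list[BirdRecord], list[BirdRecord]]:
    """Record-level train/test split; disjoint, exhaustive, seeded.

    Stratified by 7-day age band by default so every age range appears
    in both subsets; pass ``stratify_by_band=False`` for a plain random
    split.
    """
    n = len(records)
    if n < 2:
        raise ValueError("too few records to populate both subsets")
    rng = np.random.default_rng(seed)
    indices = np.arange(n)
    test_idx: list[int] = []
    if stratify_by_band:
        groups: dict[int, list[int]] = {}
        for i, r in enumerate(records):
            groups.setdefault(_band_index(r.day), []).append(i)
        for idxs in groups.values():
            idxs = np.array(idxs)
            rng.shuffle(idxs)
            k = int(round(len(idxs) * test_fraction))
            test_idx.extend(idxs[:k].tolist())
    else:
        rng.shuffle(indices)
        k = int(round(n * test_fraction))
        test_idx = indices[:k].tolist()
    test_set = set(test_idx)
    if not test_set or len(test_set) == n:
        raise ValueError("split leaves a subset empty; adjust test_fraction")
    train = [records[i] for i in range(n) if i not in test_set]
    test = [records[i] for i in sorted(test_set)]
    return train, test


def _features(records: Sequence[BirdRecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[r.back_length, r.back_width] for r in records], dtype=float)
    y = np.array([r.live_weight for r in records], dtype=float)
    return X, y


def _record_keys(records: Sequence[BirdRecord]) -> set[tuple[str, int]]:
    return {(r.bird_id, r.day) for r in records}


def tune_and_evaluate(records: Sequence[BirdRecord], config: BenchmarkConfig) -> EvaluationReport:
    """Run the full repeated tuning/evaluation protocol.

    Per repeat: fresh stratified split; grid-search CV on a 90% tuning
    subset of the training data (selection metric: CV RMSE); winner
    retrained on the entire training set; metrics on the held-out test
    set. Tuning never sees the test subset — asserted by record-id
    bookkeeping. Mean |Shapley| per feature is computed on a sample of
    test instances against a training background.
    """
    config.validate()
    if config.dataset != "mixed":
        records = [r for r in records if r.sex == config.dataset]
    if not records:
        raise ValueError(f"no records for dataset {config.dataset!r}")

    rows = []
    shap_rows = []
    for rep in range(config.n_repeats):
        rep_seed = config.seed + 1000 * rep
        train, test = split_records(
            records, config.test_fraction, seed=rep_seed, stratify_by_band=config.stratify_by_band
        )
        assert not (_record_keys(train) & _record_keys(test)), "train/test leak"

        X_train, y_train = _features(train)
        X_test, y_test = _features(test)
        scaler = MinMaxScaler2().fit(X_train)
        Xs_train = scaler.transform(X_train)
        Xs_test = scaler.transform(X_test)

        rng = np.random.default_rng(rep_seed)
        n_tune = int(round(len(train) * config.tuning_fraction_of_train))
        tune_idx = rng.permutation(len(train))[:n_tune]

        for algo in config.algorithms:
            grid = config.grids.get(algo, {})
            est = _make_estimator(algo, seed=rep_seed)
            if grid:
                if n_tune < config.cv_folds * 2:
                    raise ValueError("tuning subset too small for CV folds")
                search = GridSearchCV(
                    est,
                    grid,
                    cv=KFold(config.cv_folds, shuffle=True, random_state=rep_seed),
                    scoring="neg_root_mean_squared_error",
                    n_jobs=1,
                )
                search.fit(Xs_train[tune_idx], y_train[tune_idx])
                best_params = search.best_params_
                model = clone(est).set_params(**best_params)
            else:
                best_params = {}
                model = clone(est)
            model.fit(Xs_train, y_train)

            pred_train = model.predict(Xs_train)
            pred_test = model.predict(Xs_test)
            rows.append(
                {
                    "dataset": config.dataset,
                    "algorithm": algo,
                    "repeat": rep,
                    "r2_train": metrics.r_squared(y_train, pred_train),
                    "rmse_train_g": metrics.rmse(y_train, pred_train),
                    "mape_train_pct": metrics.mape(y_train, pred_train),
                    "r2_test": metrics.r_squared(y_test, pred_test),
                    "rmse_test_g": metrics.rmse(y_test, pred_test),
                    "mape_test_pct": metrics.mape(y_test, pred_test),
                    "best_params": repr(best_params),
                }
            )

            if rep == 0 and config.shapley_instances > 0:
                bg = Xs_train[
                    rng.choice(len(Xs_train), min(config.shapley_background, len(Xs_train)), replace=False)
                ]
                inst_idx = rng.choice(
                    len(Xs_test), min(config.shapley_instances, len(Xs_test)), replace=False
                )
                phis = np.array(
                    [shapley_two_feature(model.predict, Xs_test[i], bg)[:2] for i in inst_idx]
                )
                mean_abs = np.abs(phis).mean(axis=0)
                shap_rows.append(
                    {
                        "dataset": config.dataset,
                        "algorithm": algo,
                        "mean_abs_shap_length": mean_abs[0],
                        "mean_abs_shap_width": mean_abs[1],
                    }
                )

    report = EvaluationReport(
        results=pd.DataFrame(rows), shapley=pd.DataFrame(shap_rows), config=config
    )
    expected = len(config.algorithms) * config.n_repeats
    assert len(report.results) == expected, "report cardinality mismatch"
    return report


def shapley_two_feature(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instance: np.ndarray,
    background: np.ndarray,
) -> tuple[float, float, float]:
    """Exact Shapley values for a two-feature model.

    Coalitions are background-marginalized (interventional): a feature
    outside the coalition is replaced by its value in each background
    row and predictions averaged. With two features the exact value is
    the mean over the two orderings:

        phi_0 = 1/2 * [ (E_b f(x0, b1) - E_b f(b0, b1))
                      + (f(x0, x1)    - E_b f(b0, x1)) ]

    and symmetrically for feature 1. Returns (phi_0, phi_1, base_value)
    where base_value = E_b f(b0, b1).
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if instance.shape[0] != 2 or background.shape[1] != 2:
        raise ValueError("shapley_two_feature requires exactly two features")
    if background.shape[0] == 0:
        raise ValueError("background set is empty")

    def mean_pred(X: np.ndarray) -> float:
        return float(np.mean(predict_fn(X)))

    base = mean_pred(background)
    x0_b1 = background.copy()
    x0_b1[:, 0] = instance[0]
    b0_x1 = background.copy()
    b0_x1[:, 1] = instance[1]
    v_x0 = mean_pred(x0_b1)  # v({0})
    v_x1 = mean_pred(b0_x1)  # v({1})
    v_full = float(np.mean(predict_fn(instance[None, :])))

    phi0 = 0.5 * ((v_x0 - base) + (v_full - v_x1))
    phi1 = 0.5 * ((v_x1 - base) + (v_full - v_x0))
    return phi0, phi1, base
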