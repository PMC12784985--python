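"""Log-transformed pixel-area regression.

Model: ``log(LW) = b0 + b1*Day + b2*log(P) + b3*(Day * log(P))`` where P
is the projected foreground pixel count and LW the live weight in grams.
Fitted by ordinary least squares on a training subset; RMSE and MAPE are
reported in grams after back-transforming predictions. Log base defaults
to 10 and is recorded in the model artifact so generators and fitted
models always agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from broilerweight import metrics

if TYPE_CHECKING:  # pragma: no cover
    from broilerweight.synthetic_data import BirdRecord

__all__ = [
    "REFERENCE_COEFFICIENTS",
    "LogPixelModel",
    "WeeklyErrorTable",
    "fit_log_model",
    "predict_weight",
    "weekly_errors",
    "WEEK_BANDS",
]

# Reference coefficient sets (b0, b1, b2, b3) per group; also the
# defaults used by the synthetic generator to invert pixel areas.
REFERENCE_COEFFICIENTS: dict[str, tuple[float, float, float, float]] = {
    "male": (-4.127, 0.124, 1.261, -0.020),
    "female": (-4.380, 0.127, 1.318, -0.021),
    "mixed": (-4.294, 0.124, 1.299, -0.021),
}

WEEK_BANDS: tuple[tuple[int, int], ...] = (
    (1, 7),
    (8, 14),
    (15, 21),
    (22, 28),
    (29, 35),
    (36, 42),
)


def _check_reference_monotone() -> None:
    # predicted grams must increase in P at every age, i.e. b2 + b3*day > 0
    for group, (_, _, b2, b3) in REFERENCE_COEFFICIENTS.items():
        slopes = b2 + b3 * np.arange(1, 43)
        if np.any(slopes <= 0):
            raise AssertionError(
                f"reference coefficients for {group!r} lose monotonicity in P"
            )


_check_reference_monotone()


@dataclass
class LogPixelModel:
    """Fitted log-pixel regression for one group.

    Coefficients are ordered (intercept, Day, logP, Day*logP); standard
    errors and two-sided p-values come from the plain OLS covariance.
    """

    group: str
    b0: float
    b1: float
    b2: float
    b3: float
    se: tuple[float, float, float, float]
    p_values: tuple[float, float, float, float]
    log_base: float = 10.0
    r2_train: float = np.nan
    rmse_train_g: float = np.nan
    mape_train_pct: float = np.nan
    r2_test: float = np.nan
    rmse_test_g: float = np.nan
    mape_test_pct: float = np.nan
    n_train: int = 0
    n_test: int = 0
    split_seed: Optional[int] = None

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.b0, self.b1, self.b2, self.b3)

    def to_json(self, path: str) -> None:
        payload = {
            "group": self.group,
            "coefficients": list(self.coefficients),
            "standard_errors": list(self.se),
            "p_values": list(self.p_values),
            "log_base": self.log_base,
            "metrics": {
                "r2_train": self.r2_train,
                "rmse_train_g": self.rmse_train_g,
                "mape_train_pct": self.mape_train_pct,
                "r2_test": self.r2_test,
                "rmse_test_g": self.rmse_test_g,
                "mape_test_pct": self.mape_test_pct,
            },
            "n_train": self.n_train,
            "n_test": self.n_test,
            "split_seed": self.split_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path: str) -> "LogPixelModel":
        with open(path) as fh:
            d = json.load(fh)
        m = d["metrics"]
        return cls(
            group=d["group"],
            b0=d["coefficients"][0],
            b1=d["coefficients"][1],
            b2=d["coefficients"][2],
            b3=d["coefficients"][3],
            se=tuple(d["standard_errors"]),
            p_values=tuple(d["p_values"]),
            log_base=d["log_base"],
            r2_train=m["r2_train"],
            rmse_train_g=m["rmse_train_g"],
            mape_train_pct=m["mape_train_pct"],
            r2_test=m["r2_test"],
            rmse_test_g=m["rmse_test_g"],
            mape_test_pct=m["mape_test_pct"],
            n_train=d["n_train"],
            n_test=d["n_test"],
            split_seed=d.get("split_seed"),
        )


@dataclass
class WeeklyErrorTable:
    """Per-band RMSE/MAPE over the six 7-day age bands."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path: str) -> None:
        self.rows.to_csv(path, index=False)


def _records_to_arrays(records: Sequence["BirdRecord"]):
    day = np.array([r.day for r in records], dtype=float)
    pix = np.array(
        [r.pixel_area if r.pixel_area is not None else np.nan for r in records],
        dtype=float,
    )
    lw = np.array([r.live_weight for r in records], dtype=float)
    return day, pix, lw


def _design(day: np.ndarray, log_p: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(day), day, log_p, day * log_p])


def fit_log_model(
    train_records: Sequence["BirdRecord"],
    test_records: Optional[Sequence["BirdRecord"]] = None,
    group: str = "mixed",
    log_base: float = 10.0,
    split_seed: Optional[int] = None,
) -> LogPixelModel:
    """OLS fit of logLW on (1, Day, logP, Day*logP) over the training set.

    Test metrics are computed only when ``test_records`` is given and
    only on those records; RMSE/MAPE are on back-transformed grams.

    Raises ``ValueError`` for non-positive weights/pixel areas (listing
    the offending rows) or a rank-deficient design (e.g. a single day).
    """
    day, pix, lw = _records_to_arrays(train_records)
    bad = np.where(~(pix > 0) | ~(lw > 0))[0]
    if bad.size:
        raise ValueError(
            "non-positive pixel_area or live_weight at training rows "
            f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
        )
    ln_base = np.log(log_base)
    log_p = np.log(pix) / ln_base
    log_lw = np.log(lw) / ln_base
    X = _design(day, log_p)
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError(
            "rank-deficient design: need variation in both Day and pixel_area"
        )

    ols = sm.OLS(log_lw, X).fit()
    b = ols.params
    pred_train = log_base ** (X @ b)
    model = LogPixelModel(
        group=group,
        b0=float(b[0]),
        b1=float(b[1]),
        b2=float(b[2]),
        b3=float(b[3]),
        se=tuple(float(s) for s in ols.bse),
        p_values=tuple(float(p) for p in ols.pvalues),
        log_base=log_base,
        r2_train=metrics.r_squared(lw, pred_train),
        rmse_train_g=metrics.rmse(lw, pred_train),
        mape_train_pct=metrics.mape(lw, pred_train),
        n_train=len(train_records),
        split_seed=split_seed,
    )

    if test_records:
        day_t, pix_t, lw_t = _records_to_arrays(test_records)
        if np.any(~(pix_t > 0)) or np.any(~(lw_t > 0)):
            raise ValueError("non-positive pixel_area or live_weight in test records")
        pred_test = predict_weight(model, day_t, pix_t)
        model.r2_test = metrics.r_squared(lw_t, pred_test)
        model.rmse_test_g = metrics.rmse(lw_t, pred_test)
        model.mape_test_pct = metrics.mape(lw_t, pred_test)
        model.n_test = len(test_records)
    return model


def predict_weight(model: LogPixelModel, day, pixel_area) -> np.ndarray | float:
    """Back-transformed prediction in grams; strictly positive.

    Days outside [1, 42] are allowed (extrapolation) — callers that care
    should range-check; pixel_area must be positive.
    """
    day_arr = np.asarray(day, dtype=float)
    pix_arr = np.asarray(pixel_area, dtype=float)
    if np.any(pix_arr <= 0):
        raise ValueError("pixel_area must be positive")
    log_p = np.log(pix_arr) / np.log(model.log_base)
    log_lw = model.b0 + model.b1 * day_arr + model.b2 * log_p + model.b3 * day_arr * log_p
    out = model.log_base**log_lw
    if np.isscalar(day) and np.isscalar(pixel_area):
        return float(out)
    return out


def weekly_errors(
    model: LogPixelModel, test_records: Sequence["BirdRecord"]
) -> WeeklyErrorTable:
    """Stratify test residuals (grams) into six 7-day age bands.

    Empty bands produce a row with n=0 and NaN metrics.
    """
    day, pix, lw = _records_to_arrays(test_records)
    bands_hit = {next(b for b in WEEK_BANDS if b[0] <= d <= b[1]) for d in day}
    if len(bands_hit) < 2:
        raise ValueError("test records must span at least 2 weekly bands")
    pred = np.asarray(predict_weight(model, day, pix), dtype=float)
    rows = []
    for lo, hi in WEEK_BANDS:
        sel = (day >= lo) & (day <= hi)
        n = int(sel.sum())
        if n == 0:
            rows.append({"day_band": f"{lo}-{hi}", "rmse_g": np.nan, "mape_pct": np.nan, "n": 0})
            continue
        rows.append(
            {
                "day_band": f"{lo}-{hi}",
                "rmse_g": metrics.rmse(lw[sel], pred[sel]),
                "mape_pct": metrics.mape(lw[sel], pred[sel]),
                "n": n,
            }
        )
    return WeeklyErrorTable(rows=pd.DataFrame(rows))
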