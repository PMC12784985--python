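"""Model performance criteria: R^2, RMSE and MAPE.

All three use population denominators (n), no degrees-of-freedom
adjustment. Inputs are paired observed/predicted series in grams (or any
common unit); MAPE additionally requires nonzero observed values.
"""

from __future__ import annotations

import numpy as np
import numpy.typing as npt

__all__ = ["r_squared", "rmse", "mape"]


def _paired(y_mea, y_pre) -> tuple[npt.NDArray[np.float64], npt.NDArray[np.float64]]:
    y_mea = np.asarray(y_mea, dtype=float)
    y_pre = np.asarray(y_pre, dtype=float)
    if y_mea.ndim != 1 or y_pre.ndim != 1:
        raise ValueError("y_mea and y_pre must be one-dimensional")
    if y_mea.shape != y_pre.shape:
        raise ValueError(
            f"length mismatch: {y_mea.shape[0]} observed vs {y_pre.shape[0]} predicted"
        )
    if y_mea.size == 0:
        raise ValueError("empty series")
    return y_mea, y_pre


def r_squared(y_mea, y_pre) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    May be negative for predictors worse than the observed mean.
    Raises ``ValueError`` when the observed series is constant (the
    denominator is undefined).
    """
    y_mea, y_pre = _paired(y_mea, y_pre)
    ss_tot = float(np.sum((y_mea - y_mea.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((y_mea - y_pre) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y_mea, y_pre) -> float:
    """Root mean square error, in the units of the inputs."""
    y_mea, y_pre = _paired(y_mea, y_pre)
    return float(np.sqrt(np.mean((y_mea - y_pre) ** 2)))


def mape(y_mea, y_pre) -> float:
    """Mean absolute percentage error, in percent.

    Raises ``ValueError`` if any observed value is zero.
    """
    y_mea, y_pre = _paired(y_mea, y_pre)
    if np.any(y_mea == 0):
        raise ValueError("MAPE undefined: observed series contains zeros")
    return float(np.mean(np.abs((y_mea - y_pre) / y_mea)) * 100.0)
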