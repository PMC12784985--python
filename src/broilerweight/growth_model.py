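"""Richards sigmoidal growth model: evaluation and nonlinear fitting.

The model is ``LW(t) = A * (1 + B * exp(-k*t)) ** (-1/m)`` with
asymptotic weight ``A`` (g), integration constant ``B``, growth-rate
constant ``k`` (per day) and dimensionless shape parameter ``m``.
Fitting is trust-region nonlinear least squares with a multi-start grid
over (k, m) to escape local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from broilerweight import metrics

__all__ = [
    "RichardsParams",
    "GrowthFitResult",
    "richards_evaluate",
    "fit_richards",
]

# multi-start grid; the objective is multimodal in (k, m)
_K_STARTS = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
_M_STARTS = (0.3, 1.0, 3.0)


@dataclass(frozen=True)
class RichardsParams:
    """Parameters of the Richards growth function.

    A > 0 is the asymptote in grams; with B, k, m > 0 the curve is
    strictly increasing in t and tends to A.
    """

    A: float
    B: float
    k: float
    m: float

    def validate(self) -> None:
        if self.A <= 0:
            raise ValueError(f"asymptote A must be positive, got {self.A}")
        if self.k <= 0:
            raise ValueError(f"growth-rate constant k must be positive, got {self.k}")
        if self.m <= 0:
            raise ValueError(f"shape parameter m must be positive, got {self.m}")
        if self.B < 0:
            raise ValueError(f"integration constant B must be >= 0, got {self.B}")


@dataclass
class GrowthFitResult:
    params: RichardsParams
    r2: float
    rmse_g: float
    mape_pct: float
    converged: bool
    n_obs: int
    group: str = "mixed"
    sse: float = field(default=np.nan)


def richards_evaluate(params: RichardsParams, t) -> np.ndarray | float:
    """Evaluate the Richards curve at age(s) ``t`` (days); returns grams."""
    params.validate()
    t_arr = np.asarray(t, dtype=float)
    base = 1.0 + params.B * np.exp(-params.k * t_arr)
    if np.any(base <= 0):
        raise ValueError("1 + B*exp(-k*t) must be positive")
    out = params.A * base ** (-1.0 / params.m)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _residuals(theta: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    a, b, k, m = theta
    return a * (1.0 + b * np.exp(-k * t)) ** (-1.0 / m) - w


def fit_richards(
    t: Iterable[float],
    weights: Iterable[float],
    group: str = "mixed",
    k_starts: Sequence[float] = _K_STARTS,
    m_starts: Sequence[float] = _M_STARTS,
) -> GrowthFitResult:
    """Fit the Richards function to (age, live weight) pairs.

    Pooled nonlinear least squares; deterministic given the data and the
    start grid. A is bounded to (max observed weight, 20*max] to prevent
    degenerate exponential fits. Non-convergence from every start is
    reported via ``converged=False``, never silently.

    Parameters
    ----------
    t, weights : day indices and live weights (g), equal length.
    group : label carried through to the result.
    """
    t = np.asarray(list(t), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if t.shape != w.shape:
        raise ValueError("t and weights must have equal length")
    if np.unique(t).size < 8:
        raise ValueError("need at least 8 distinct days to fit a 4-parameter curve")
    if np.any(w <= 0):
        raise ValueError("live weights must be positive")

    w_max = float(w.max())
    lo = np.array([w_max * (1 + 1e-9), 1e-9, 1e-4, 1e-3])
    hi = np.array([w_max * 20.0, 1e9, 2.0, 50.0])
    t_min = float(t.min())
    w_at_tmin = float(w[np.argmin(t)])

    best = None
    for k0 in k_starts:
        for m0 in m_starts:
            a0 = min(max(2.0 * w_max, lo[0] * 1.01), hi[0])
            # choose B so the start curve passes through the earliest point
            ratio = max((a0 / w_at_tmin) ** m0 - 1.0, 1e-6)
            b0 = float(np.clip(ratio * np.exp(k0 * t_min), lo[1], hi[1]))
            x0 = np.clip([a0, b0, k0, m0], lo, hi)
            try:
                sol = least_squares(
                    _residuals, x0, bounds=(lo, hi), args=(t, w), method="trf"
                )
            except Exception:
                continue
            if not sol.success:
                continue
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0]:
                best = (sse, sol.x)

    if best is None:
        params = RichardsParams(w_max * 2, 1.0, 0.1, 1.0)
        return GrowthFitResult(
            params=params,
            r2=np.nan,
            rmse_g=np.nan,
            mape_pct=np.nan,
            converged=False,
            n_obs=t.size,
            group=group,
        )

    sse, (a, b, k, m) = best
    params = RichardsParams(A=float(a), B=float(b), k=float(k), m=float(m))
    pred = richards_evaluate(params, t)
    return GrowthFitResult(
        params=params,
        r2=metrics.r_squared(w, pred),
        rmse_g=metrics.rmse(w, pred),
        mape_pct=metrics.mape(w, pred),
        converged=True,
        n_obs=int(t.size),
        group=group,
        sse=sse,
    )
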