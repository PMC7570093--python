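"""Nonlinear least-squares estimation of the state-diagram curve parameters.

``fit_gordon_taylor`` estimates (Tgs, K) from glass-transition
observations in the unfreezable-water domain; ``fit_chen`` estimates
(E, B) from freezing points in the freezable domain.  Both minimise
unweighted squared residuals in degC, matching how such transition data
are conventionally regressed, and report the coefficient of
determination R^2 about the observation mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .core_models import (
    ChenParams,
    Composition,
    DomainError,
    GordonTaylorParams,
    chen_tm,
    gordon_taylor_tg,
)

__all__ = ["ThermalDataset", "FitResult", "fit_gordon_taylor", "fit_chen", "r_squared"]

# Termination: 1e-10 on the sum of squares, 500 evaluations; on failure,
# 5 jittered restarts before the result is flagged unconverged.
_FTOL = 1e-10
_MAX_NFEV = 500
_N_RESTARTS = 5


def _as_points(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (ws, temperature_c) pairs")
    return arr


@dataclass
class ThermalDataset:
    """Moisture-series thermal transitions for one sample.

    ``tg_points``/``tm_points`` are (ws, degC) pairs from the
    unfreezable- and freezable-water domains respectively;
    ``tg_prime_obs``/``tm_prime_obs`` are the replicated transition
    temperatures of the maximally freeze-concentrated phase.
    """

    sample_id: str
    composition: Optional[Composition] = None
    tg_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    tm_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    tg_prime_obs: list[float] = field(default_factory=list)
    tm_prime_obs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tg_points = _as_points(self.tg_points)
        self.tm_points = _as_points(self.tm_points)
        for arr, name in ((self.tg_points, "tg_points"), (self.tm_points, "tm_points")):
            if arr.size and (arr[:, 0].min() < 0.0 or arr[:, 0].max() > 1.0):
                raise DomainError(f"{name}: solids fractions must lie in [0, 1]")


@dataclass
class FitResult:
    """Estimated curve parameters with goodness of fit."""

    params: Union[GordonTaylorParams, ChenParams]
    r_squared: float
    residuals: np.ndarray
    n_obs: int
    converged: bool
    sse: float

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.size != self.n_obs:
            raise ValueError("residual count must equal n_obs")


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSE/SST, SST about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-d, n >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observations have zero total variance; R^2 undefined")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def _check_design(ws: np.ndarray, n_min: int, label: str) -> None:
    if ws.size < n_min:
        raise ValueError(
            f"{label}: need at least {n_min} points for 2 parameters, got {ws.size}"
        )
    if np.ptp(ws) == 0.0:
        raise ValueError(f"{label}: all ws values equal; design is degenerate")


def _solve(
    residual_fn, x0: np.ndarray, bounds: tuple, rng_seed: int = 0
) -> tuple[np.ndarray, bool]:
    """least_squares with jittered multi-start on non-convergence."""
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    best_x, best_cost, converged = None, np.inf, False
    rng = np.random.default_rng(rng_seed)
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(_N_RESTARTS):
        jitter = x0 * rng.uniform(0.5, 1.5, size=len(x0)) + rng.normal(
            0.0, 0.05 * (hi - lo).clip(max=10.0)
        )
        starts.append(np.clip(jitter, lo + 1e-8, hi - 1e-8))
    for i, start in enumerate(starts):
        sol = least_squares(
            residual_fn,
            start,
            bounds=(lo, hi),
            ftol=_FTOL,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=_MAX_NFEV,
        )
        if sol.cost < best_cost:
            best_x, best_cost = sol.x, sol.cost
            converged = bool(sol.success)
        if sol.success and i == 0:
            break  # first start already converged; no restarts needed
    return best_x, converged


def fit_gordon_taylor(data: ThermalDataset) -> FitResult:
    """Least-squares (Tgs, K) from the (ws, Tg) series of ``data``.

    Starts at Tgs = max observed Tg, K = 4; bounds Tgs in (-50, 250) degC,
    K in (0.1, 50).  Non-convergence after restarts is flagged on the
    result, never silent.
    """
    ws, tg = data.tg_points[:, 0], data.tg_points[:, 1]
    _check_design(ws, 3, "tg_points")

    def resid(x: np.ndarray) -> np.ndarray:
        return gordon_taylor_tg(ws, GordonTaylorParams(tgs=x[0], k=x[1])) - tg

    x0 = np.array([max(tg.max(), -49.0), 4.0])
    x, converged = _solve(resid, x0, bounds=([-50.0, 0.1], [250.0, 50.0]))
    params = GordonTaylorParams(tgs=float(x[0]), k=float(x[1]))
    pred = gordon_taylor_tg(ws, params)
    res = tg - pred
    return FitResult(
        params=params,
        r_squared=r_squared(tg, pred),
        residuals=res,
        n_obs=ws.size,
        converged=converged,
        sse=float(np.sum(res**2)),
    )


def fit_chen(data: ThermalDataset) -> FitResult:
    """Least-squares (E, B) from the (ws, Tm) series of ``data``.

    The search is constrained so the log argument of the Chen curve stays
    positive at every data point: B < (1 - ws)/ws for the largest ws.
    Starts at E = 0.05, B = 0.15.
    """
    ws, tm = data.tm_points[:, 0], data.tm_points[:, 1]
    _check_design(ws, 3, "tm_points")
    ws_hi = ws.max()
    # Domain requires 1 - ws - b*ws > 0 at every observation.
    b_cap = min(0.99, (1.0 - ws_hi) / ws_hi - 1e-9) if ws_hi > 0 else 0.99
    if b_cap <= 0.0:
        raise DomainError(
            f"largest data ws={ws_hi:.6g} leaves no b in [0, 1) with a valid "
            "Chen domain"
        )

    def resid(x: np.ndarray) -> np.ndarray:
        return chen_tm(ws, ChenParams(e=x[0], b=x[1])) - tm

    x0 = np.array([0.05, min(0.15, 0.5 * b_cap)])
    x, converged = _solve(resid, x0, bounds=([1e-4, 0.0], [1.0, b_cap]))
    params = ChenParams(e=float(x[0]), b=float(x[1]))
    pred = chen_tm(ws, params)
    res = tm - pred
    return FitResult(
        params=params,
        r_squared=r_squared(tm, pred),
        residuals=res,
        n_obs=ws.size,
        converged=converged,
        sse=float(np.sum(res**2)),
    )
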