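"""Maximal-freeze-concentration condition and state-diagram assembly.

On slow freezing, solutes concentrate in an unfrozen phase until ice
formation stops; the condition reached is described by the glass
transition Tg', the onset-of-ice-melting temperature Tm', and the
solids fraction ws' of that maximally freeze-concentrated phase.
Tg' and Tm' vary little with the initial moisture content, so each is
taken as the unweighted average of its replicate observations; ws' is
located as the intersection of the averaged Tm' level with the fitted
Chen freezing curve, which is strictly decreasing and hence crosses any
Tm' < Tw exactly once.

Tg' is the measured average and is *not* recomputed from the
Gordon--Taylor curve at ws': measured Tg' and the curve routinely
disagree by several degC, so consistency between them is not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .core_models import (
    ChenParams,
    Composition,
    DomainError,
    StateDiagram,
    chen_tm,
    chen_ws_max,
    gordon_taylor_tg,
)
from .curve_fitting import FitResult

__all__ = ["MFCC", "average_transition", "solve_ws_prime", "build_state_diagram", "tabulate_curves"]

# Bracketing tolerance on ws for the Tm' intersection.
_WS_XTOL = 1e-12


@dataclass(frozen=True)
class MFCC:
    """The maximal-freeze-concentration triple (Tg', Tm', ws').

    ``tg_prime`` may be None when the transition was not detected
    (it can be masked by ice melting in high-polymer samples).
    """

    tg_prime: Optional[float]
    tm_prime: float
    ws_prime: float

    def __post_init__(self) -> None:
        if self.tg_prime is not None and self.tg_prime > self.tm_prime:
            raise DomainError(
                f"tg_prime={self.tg_prime!r} exceeds tm_prime={self.tm_prime!r}"
            )
        if not (0.0 < self.ws_prime < 1.0):
            raise DomainError(f"ws_prime={self.ws_prime!r} outside (0, 1)")


def average_transition(observations: Sequence[float]) -> float:
    """Unweighted arithmetic mean of replicate transition temperatures (degC)."""
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ValueError("cannot average an empty list of observations")
    return float(obs.mean())


def solve_ws_prime(chen: ChenParams, tm_prime: float) -> float:
    """Solids fraction where the Chen curve crosses the ``tm_prime`` level.

    Bisection on (0, ws_max); the curve is strictly decreasing, so the
    root is unique.  Requires ``tm_prime < tw`` (some freezing-point
    depression must have occurred).
    """
    if not (tm_prime < chen.tw):
        raise DomainError(
            f"tm_prime={tm_prime!r} must lie below the pure-water freezing "
            f"point tw={chen.tw!r}"
        )
    ws_max = chen_ws_max(chen)
    lo, hi = 1e-9, ws_max - 1e-9

    def f(ws: float) -> float:
        return chen_tm(ws, chen) - tm_prime

    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo > 0.0 > f_hi):
        raise DomainError(
            f"no sign change on ({lo:g}, {hi:g}): f(lo)={f_lo:.3g}, "
            f"f(hi)={f_hi:.3g}; tm_prime may be unreachable"
        )
    return float(bisect(f, lo, hi, xtol=_WS_XTOL))


def build_state_diagram(
    gt_fit: FitResult,
    chen_fit: FitResult,
    tg_prime_obs: Sequence[float],
    tm_prime_obs: Sequence[float],
    composition: Composition,
) -> StateDiagram:
    """Assemble a state diagram from fitted curves and prime observations.

    Tg'/Tm' are averaged over their replicates; ws' is solved from the
    averaged Tm' on the fitted Chen curve.  An empty ``tg_prime_obs`` is
    allowed (undetected transition); an empty ``tm_prime_obs`` is not.
    """
    for fit, label in ((gt_fit, "Gordon-Taylor"), (chen_fit, "Chen")):
        if not fit.converged:
            raise ValueError(f"{label} fit did not converge; cannot build diagram")
    if len(tm_prime_obs) == 0:
        raise ValueError("tm_prime observations are required to locate ws'")
    tm_prime = average_transition(tm_prime_obs)
    tg_prime = average_transition(tg_prime_obs) if len(tg_prime_obs) else None
    ws_prime = solve_ws_prime(chen_fit.params, tm_prime)
    return StateDiagram(
        composition=composition,
        gt=gt_fit.params,
        chen=chen_fit.params,
        mfcc=MFCC(tg_prime=tg_prime, tm_prime=tm_prime, ws_prime=ws_prime),
    )


def tabulate_curves(diagram: StateDiagram, n_points: int) -> pd.DataFrame:
    """Evaluate both curves on an even ws grid over [0, 1].

    Returns columns ``ws``, ``tg_c`` and ``tm_c``; the freezing curve is
    NaN wherever ws is at or beyond the Chen domain boundary 1/(1+B).
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    ws = np.linspace(0.0, 1.0, n_points)
    tg = gordon_taylor_tg(ws, diagram.gt)
    ws_max = chen_ws_max(diagram.chen)
    tm = np.full_like(ws, np.nan)
    valid = ws < ws_max
    tm[valid] = chen_tm(ws[valid], diagram.chen)
    return pd.DataFrame({"ws": ws, "tg_c": tg, "tm_c": tm})
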