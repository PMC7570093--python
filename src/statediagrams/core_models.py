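"""Thermodynamic models underlying food state diagrams.

A state diagram maps the physical states of a solids--water mixture
(glassy, rubbery, frozen, liquid) over the full solids-mass-fraction x
temperature plane.  Two curves and one point define it:

* the glass-transition curve Tg(ws), modelled by the Gordon--Taylor
  equation -- a weighted mean of the anhydrous-solids transition ``Tgs``
  and the amorphous-water transition ``Tgw`` (-135 degC) with interaction
  constant ``K``;
* the freezing curve Tm(ws), modelled by the Chen freezing-point-
  depression equation with the water-to-solids molecular-mass ratio
  ``E`` and the unfreezable-water ratio ``B``;
* the maximal-freeze-concentration condition (Tg', Tm', ws') -- see
  :mod:`statediagrams.state_diagram`.

Temperatures are carried in degrees Celsius throughout.  The
Gordon--Taylor expression is a weighted mean and therefore affine-
invariant: evaluating it in degC or in K gives the same answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Union

import numpy as np

if TYPE_CHECKING:  # avoids a runtime cycle; MFCC lives in state_diagram
    from .state_diagram import MFCC

__all__ = [
    "DomainError",
    "Composition",
    "GordonTaylorParams",
    "ChenParams",
    "StateDiagram",
    "gordon_taylor_tg",
    "chen_tm",
    "chen_ws_max",
    "TGW_DEFAULT_C",
    "BETA_WATER",
    "LAMBDA_WATER",
]

#: Glass transition of amorphous water, degC.  A literature constant,
#: never fitted.
TGW_DEFAULT_C: float = -135.0

#: Molar freezing-point constant of water, kg K / kgmol.
BETA_WATER: float = 1860.0

#: Molecular mass of water, kg / kgmol.
LAMBDA_WATER: float = 18.015

ArrayLike = Union[float, np.ndarray]


class DomainError(ValueError):
    """An input lies outside the physical/mathematical domain of a model."""


COMPONENTS = ("xf", "xg", "xs", "xp", "xa", "xm")
COMPONENT_NAMES = {
    "xf": "fructose",
    "xg": "glucose",
    "xs": "sucrose",
    "xp": "pectin",
    "xa": "citric acid",
    "xm": "maltodextrin",
}


@dataclass(frozen=True)
class Composition:
    """Dry-basis mass fractions of the six solutes of a model juice.

    Fractions must each lie in [0, 1] and sum to 1 within ``sum_tol``.
    The default tolerance is strict (1e-9); printed design tables rounded
    to three decimals may need ``sum_tol=2e-3``.
    """

    xf: float  # fructose
    xg: float  # glucose
    xs: float  # sucrose
    xp: float  # pectin
    xa: float  # citric acid
    xm: float  # maltodextrin
    sum_tol: float = field(default=1e-9, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(
                    f"{COMPONENT_NAMES[name]} fraction {name}={v!r} outside [0, 1]"
                )
        total = sum(self.as_tuple())
        if abs(total - 1.0) > self.sum_tol:
            raise DomainError(
                f"mass fractions sum to {total:.6g}, not 1 within {self.sum_tol:g}"
            )

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.xf, self.xg, self.xs, self.xp, self.xa, self.xm)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPONENTS}


@dataclass(frozen=True)
class GordonTaylorParams:
    """Parameters of the Gordon--Taylor glass-transition curve.

    ``tgs`` is the anhydrous-solids glass transition (degC), ``k`` the
    dimensionless water--solids interaction constant, ``tgw`` the glass
    transition of amorphous water (fixed at -135 degC unless overridden).
    """

    tgs: float
    k: float
    tgw: float = TGW_DEFAULT_C

    def __post_init__(self) -> None:
        if not (self.k > 0.0):
            raise DomainError(f"interaction constant k={self.k!r} must be > 0")
        if not (self.tgs > self.tgw):
            raise DomainError(
                f"tgs={self.tgs!r} must exceed tgw={self.tgw!r} degC"
            )


@dataclass(frozen=True)
class ChenParams:
    """Parameters of the Chen freezing-point-depression curve.

    ``e`` is the water-to-solids molecular mass ratio (lambda_w/lambda_s),
    ``b`` the ratio of unfreezable water to total solids.  ``tw`` is the
    freezing point of pure water (degC), ``beta`` the molar freezing-point
    constant and ``lambda_w`` the molecular mass of water -- physical
    constants, not fitted.
    """

    e: float
    b: float
    tw: float = 0.0
    beta: float = BETA_WATER
    lambda_w: float = LAMBDA_WATER

    def __post_init__(self) -> None:
        if not (self.e > 0.0):
            raise DomainError(f"mass ratio e={self.e!r} must be > 0")
        if not (0.0 <= self.b < 1.0):
            raise DomainError(f"unfreezable-water ratio b={self.b!r} outside [0, 1)")


@dataclass(frozen=True)
class StateDiagram:
    """A complete state diagram: composition, both curves, and the MFCC."""

    composition: Composition
    gt: GordonTaylorParams
    chen: ChenParams
    mfcc: "MFCC"


def gordon_taylor_tg(ws: ArrayLike, params: GordonTaylorParams) -> ArrayLike:
    """Glass transition (degC) of a solids--water mixture at solids fraction ``ws``.

    Weighted mean ``(ws*Tgs + K*(1-ws)*Tgw) / (ws + K*(1-ws))``; returns
    ``tgw`` at ws=0 and ``tgs`` at ws=1, monotone between when tgs > tgw.
    """
    ws_arr = np.asarray(ws, dtype=float)
    if np.any(ws_arr < 0.0) or np.any(ws_arr > 1.0):
        raise DomainError(f"solids fraction ws={ws!r} outside [0, 1]")
    num = ws_arr * params.tgs + params.k * (1.0 - ws_arr) * params.tgw
    den = ws_arr + params.k * (1.0 - ws_arr)
    out = num / den
    return float(out) if np.isscalar(ws) or ws_arr.ndim == 0 else out


def chen_ws_max(params: ChenParams) -> float:
    """Upper end of the valid solids domain of the Chen curve: 1/(1+B)."""
    return 1.0 / (1.0 + params.b)


def chen_tm(ws: ArrayLike, params: ChenParams) -> ArrayLike:
    """Equilibrium freezing point (degC) at solids fraction ``ws``.

    ``Tm = Tw + (beta/lambda_w) * ln((1-ws-B*ws) / (1-ws-B*ws + E*ws))``.
    Strictly decreasing on [0, ws_max) and equal to ``tw`` at ws=0;
    diverges to -inf as ws approaches ``ws_max = 1/(1+B)``.
    """
    ws_arr = np.asarray(ws, dtype=float)
    ws_max = chen_ws_max(params)
    if np.any(ws_arr < 0.0) or np.any(ws_arr >= ws_max):
        raise DomainError(
            f"solids fraction ws={ws!r} outside the Chen domain [0, ws_max) "
            f"with ws_max=1/(1+B)={ws_max:.6g}"
        )
    free = 1.0 - ws_arr - params.b * ws_arr  # freezable water fraction
    out = params.tw + (params.beta / params.lambda_w) * np.log(
        free / (free + params.e * ws_arr)
    )
    return float(out) if np.isscalar(ws) or ws_arr.ndim == 0 else out
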