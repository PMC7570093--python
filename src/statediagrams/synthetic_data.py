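"""Seeded synthetic data emulating moisture-series DSC transition studies.

The generator produces the two kinds of input the pipeline consumes:

* a moisture-series thermal dataset for one sample -- glass transitions
  on a solids grid in the unfreezable-water domain (0--19% moisture,
  i.e. ws 0.81--1.0), freezing points on a grid in the freezable domain
  (27--90% moisture, ws 0.10--0.73), and replicated Tg'/Tm'
  observations -- all evaluated from known Gordon--Taylor/Chen
  parameters with additive homoscedastic Gaussian noise in degC;
* a design-response table: one value of each of the seven responses per
  design run, evaluated from known mixture-model coefficients plus
  Gaussian noise.

A single integer seed fixes the complete output.  Real DSC data differ
in ways the generator deliberately ignores: heteroscedastic and
instrument-drift errors, annealing-protocol sensitivity of Tm', and
transition-width ambiguity in assigning midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core_models import (
    ChenParams,
    Composition,
    DomainError,
    GordonTaylorParams,
    chen_tm,
    chen_ws_max,
    gordon_taylor_tg,
)
from .curve_fitting import ThermalDataset
from .mixture_modeling import (
    MixtureDesign,
    MixtureModel,
    RESPONSE_NAMES,
    predict_response,
)

__all__ = ["GeneratorSpec", "generate_thermal_dataset", "generate_design_study"]

# Default grids: 6 moisture levels per domain, mirroring a typical
# moisture-conditioning series.  The unfreezable (glass) domain covers
# 0-19% moisture, i.e. ws 0.81-1.0.  The freezable domain spans 10-90%
# moisture -- annealed freezing-point measurements reach 20% moisture,
# ws 0.80 -- but is always capped inside the Chen domain 1/(1+B), so the
# freezing-curve grid is derived from the ground-truth parameters when
# not given explicitly.
_DEFAULT_TG_GRID = tuple(np.linspace(0.81, 1.0, 6))
_TM_GRID_LO = 0.10
_TM_GRID_HI = 0.80
_TM_GRID_DOMAIN_FRACTION = 0.95  # keep the top grid point off the divergence


def _default_tm_grid(chen: ChenParams) -> tuple[float, ...]:
    hi = min(_TM_GRID_HI, _TM_GRID_DOMAIN_FRACTION * chen_ws_max(chen))
    return tuple(np.linspace(_TM_GRID_LO, hi, 6))


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth and noise structure for one synthetic thermal study."""

    gt: GordonTaylorParams
    chen: ChenParams
    tg_prime_true: float = -50.0
    tm_prime_true: float = -35.0
    tg_ws_grid: tuple[float, ...] = _DEFAULT_TG_GRID
    tm_ws_grid: tuple[float, ...] | None = None
    noise_sd_tg: float = 1.0
    noise_sd_tm: float = 1.0
    noise_sd_primes: float = 1.5
    n_prime_replicates: int = 6
    seed: int = 0
    sample_id: str = "synthetic"
    composition: Composition | None = None

    def __post_init__(self) -> None:
        for name in ("noise_sd_tg", "noise_sd_tm", "noise_sd_primes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_prime_replicates < 1:
            raise ValueError("n_prime_replicates must be at least 1")
        if self.tm_ws_grid is None:
            object.__setattr__(self, "tm_ws_grid", _default_tm_grid(self.chen))
        ws_max = chen_ws_max(self.chen)
        bad = [w for w in self.tm_ws_grid if not (0.0 <= w < ws_max)]
        if bad:
            raise DomainError(
                f"tm_ws_grid points {bad} outside the Chen domain [0, {ws_max:.6g})"
            )
        if self.tm_prime_true >= self.chen.tw:
            raise ValueError("tm_prime_true must lie below the water freezing point")


def generate_thermal_dataset(spec: GeneratorSpec) -> ThermalDataset:
    """Draw one seeded moisture-series dataset from the spec's ground truth."""
    rng = np.random.default_rng(spec.seed)
    tg_ws = np.asarray(spec.tg_ws_grid, dtype=float)
    tm_ws = np.asarray(spec.tm_ws_grid, dtype=float)
    tg = gordon_taylor_tg(tg_ws, spec.gt) + rng.normal(0.0, spec.noise_sd_tg, tg_ws.size)
    tm = chen_tm(tm_ws, spec.chen) + rng.normal(0.0, spec.noise_sd_tm, tm_ws.size)
    n_rep = spec.n_prime_replicates
    tg_prime = spec.tg_prime_true + rng.normal(0.0, spec.noise_sd_primes, n_rep)
    tm_prime = spec.tm_prime_true + rng.normal(0.0, spec.noise_sd_primes, n_rep)
    return ThermalDataset(
        sample_id=spec.sample_id,
        composition=spec.composition,
        tg_points=np.column_stack([tg_ws, tg]),
        tm_points=np.column_stack([tm_ws, tm]),
        tg_prime_obs=list(tg_prime),
        tm_prime_obs=list(tm_prime),
    )


def generate_design_study(
    models: Mapping[str, MixtureModel],
    design: MixtureDesign,
    noise_sd: Union[float, Mapping[str, float]] = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded per-run response table from known mixture-model coefficients.

    ``noise_sd`` is either one degC-scale standard deviation for every
    response or a mapping per response name.  Columns: ``experiment``
    plus the seven response names.
    """
    missing = [r for r in RESPONSE_NAMES if r not in models]
    if missing:
        raise ValueError(f"models missing for responses: {missing}")
    unknown = [r for r in models if r not in RESPONSE_NAMES]
    if unknown:
        raise ValueError(f"unknown response names: {unknown}")
    if isinstance(noise_sd, Mapping):
        sd = {r: float(noise_sd.get(r, 0.0)) for r in RESPONSE_NAMES}
    else:
        sd = {r: float(noise_sd) for r in RESPONSE_NAMES}
    rng = np.random.default_rng(seed)
    out: dict[str, list[float]] = {r: [] for r in RESPONSE_NAMES}
    numbers = []
    for number, comp in design.runs:
        numbers.append(number)
        for r in RESPONSE_NAMES:
            y = predict_response(models[r], comp)
            out[r].append(y + rng.normal(0.0, sd[r]) if sd[r] > 0 else y)
    return pd.DataFrame({"experiment": numbers, **out})
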