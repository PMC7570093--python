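"""Bundled reference tables from the published maltodextrin study.

Three tables ship with the package: the 25-run D-optimal six-component
mixture design, the per-run fitted parameters (Tgs, K, E, B with their
R^2 values) and maximal-freeze-concentration data (Tg', Tm', ws'), and
the seven solute-composition mixture models with their ANOVA summaries.
They are transcribed verbatim from the printed tables and validated at
load: shapes, simplex sums (within printed rounding) and term labels.

The composition model for E is transcribed as printed but carries known
typesetting defects (see the JSON comment and docs/methods.md); treat
its numeric predictions with caution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .core_models import Composition
from .mixture_modeling import (
    ALL_TERMS,
    AnovaStats,
    MixtureDesign,
    MixtureModel,
    RESPONSE_NAMES,
)

__all__ = ["PaperFixtures", "load_fixtures"]

_TABLE2_COLUMNS = (
    "experiment", "tgs", "k", "r2_gt", "e", "b", "r2_chen",
    "tg_prime", "tm_prime", "ws_prime",
)


@dataclass(frozen=True)
class PaperFixtures:
    """The three bundled reference tables."""

    table1: MixtureDesign
    table2: pd.DataFrame
    table3: dict[str, MixtureModel]

    def table2_row(self, experiment: int) -> pd.Series:
        match = self.table2[self.table2["experiment"] == experiment]
        if len(match) != 1:
            raise KeyError(f"experiment {experiment} not in the parameter table")
        return match.iloc[0]


def _data_path(name: str):
    return resources.files("statediagrams.data").joinpath(name)


def load_fixtures() -> PaperFixtures:
    """Load and validate the bundled design, parameter and model tables."""
    design_df = pd.read_csv(_data_path("design_table.csv").open("r", encoding="utf-8"))
    if len(design_df) != 25:
        raise ValueError(f"design table must have 25 runs, found {len(design_df)}")
    runs = []
    for _, row in design_df.iterrows():
        comp = Composition(
            xf=row["xf"], xg=row["xg"], xs=row["xs"],
            xp=row["xp"], xa=row["xa"], xm=row["xm"],
            sum_tol=2e-3,  # printed fractions round to 3 decimals
        )
        runs.append((int(row["experiment"]), comp))
    table1 = MixtureDesign(runs=tuple(runs))

    table2 = pd.read_csv(_data_path("fitted_params_table.csv").open("r", encoding="utf-8"))
    if tuple(table2.columns) != _TABLE2_COLUMNS:
        raise ValueError(f"parameter table columns {tuple(table2.columns)} != expected")
    if len(table2) != 25:
        raise ValueError(f"parameter table must have 25 rows, found {len(table2)}")

    with _data_path("mixture_models.json").open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    table3: dict[str, MixtureModel] = {}
    for name in RESPONSE_NAMES:
        if name not in raw:
            raise ValueError(f"mixture-model table missing response {name!r}")
        entry = raw[name]
        terms = tuple(entry["terms"])
        bad = [t for t in terms if t not in ALL_TERMS]
        if bad:
            raise ValueError(f"model {name!r} has unknown terms {bad}")
        a = entry["anova"]
        p = a["p_value"]
        if isinstance(p, str):  # censored as '<0.0001' in the printed table
            p = float(p.lstrip("<"))
        table3[name] = MixtureModel(
            response_name=name,
            terms=terms,
            coefficients=tuple(float(entry["terms"][t]) for t in terms),
            anova=AnovaStats(
                p_value=float(p),
                r_squared=float(a["r_squared"]),
                sd=float(a["sd"]),
                cv_percent=float(a["cv_percent"]),
            ),
        )
    return PaperFixtures(table1=table1, table2=table2, table3=table3)
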