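"""CSV and config serialization for thermal datasets, designs and models.

Conventions: plain UTF-8 CSV (RFC-4180), full numeric precision in
files.  Unicode minus signs (U+2212), as pasted from typeset tables, are
accepted on input and normalised to ASCII on output.  Parse errors name
the offending row.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .core_models import ChenParams, Composition, GordonTaylorParams
from .curve_fitting import FitResult, ThermalDataset
from .mixture_modeling import AnovaStats, MixtureDesign, MixtureModel, RESPONSE_NAMES

__all__ = [
    "read_thermal_dataset",
    "write_thermal_dataset",
    "read_design",
    "write_design",
    "read_responses",
    "write_responses",
    "params_to_dict",
    "params_from_dict",
    "write_params",
    "read_params",
    "write_fit_result",
    "write_mixture_model",
    "read_mixture_model",
    "write_curve_table",
]

PathLike = Union[str, Path]

_KINDS = ("tg", "tm", "tg_prime", "tm_prime")


def _clean(cell: str) -> str:
    """Normalise typeset minus signs to ASCII and strip whitespace."""
    return cell.replace("−", "-").replace("–", "-").strip()


def _parse_float(cell: str, row_no: int, path: PathLike, column: str) -> float:
    try:
        return float(_clean(cell))
    except ValueError:
        raise ValueError(
            f"{path}, row {row_no}: non-numeric value {cell!r} in column {column!r}"
        ) from None


def read_thermal_dataset(path: PathLike) -> ThermalDataset:
    """Read a dataset from CSV with columns sample_id, ws, kind, temperature_c."""
    tg_pts, tm_pts, tgp, tmp = [], [], [], []
    sample_id = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "ws", "kind", "temperature_c"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is row 1
            kind = _clean(row["kind"])
            if kind not in _KINDS:
                raise ValueError(
                    f"{path}, row {i}: invalid kind {kind!r}; expected one of {_KINDS}"
                )
            sample_id = sample_id or row["sample_id"].strip()
            temp = _parse_float(row["temperature_c"], i, path, "temperature_c")
            if kind in ("tg", "tm"):
                ws = _parse_float(row["ws"], i, path, "ws")
                (tg_pts if kind == "tg" else tm_pts).append((ws, temp))
            else:
                (tgp if kind == "tg_prime" else tmp).append(temp)
    return ThermalDataset(
        sample_id=sample_id or "",
        tg_points=np.array(tg_pts).reshape(-1, 2),
        tm_points=np.array(tm_pts).reshape(-1, 2),
        tg_prime_obs=tgp,
        tm_prime_obs=tmp,
    )


def write_thermal_dataset(data: ThermalDataset, path: PathLike) -> None:
    rows = []
    for ws, t in data.tg_points:
        rows.append((data.sample_id, repr(float(ws)), "tg", repr(float(t))))
    for ws, t in data.tm_points:
        rows.append((data.sample_id, repr(float(ws)), "tm", repr(float(t))))
    for t in data.tg_prime_obs:
        rows.append((data.sample_id, "", "tg_prime", repr(float(t))))
    for t in data.tm_prime_obs:
        rows.append((data.sample_id, "", "tm_prime", repr(float(t))))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "ws", "kind", "temperature_c"])
        writer.writerows(rows)


def read_design(path: PathLike) -> MixtureDesign:
    """Read a mixture design from CSV with columns experiment, xf..xm."""
    df = pd.read_csv(path, dtype=str)
    needed = ["experiment", "xf", "xg", "xs", "xp", "xa", "xm"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    runs = []
    for i, row in df.iterrows():
        fracs = {c: _parse_float(str(row[c]), i + 2, path, c) for c in needed[1:]}
        comp = Composition(**fracs, sum_tol=2e-3)  # printed tables round to 3 dp
        runs.append((int(row["experiment"]), comp))
    return MixtureDesign(runs=tuple(runs))


def write_design(design: MixtureDesign, path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["experiment", "xf", "xg", "xs", "xp", "xa", "xm"])
        for number, comp in design.runs:
            writer.writerow([number, *(repr(float(v)) for v in comp.as_tuple())])


def read_responses(path: PathLike) -> pd.DataFrame:
    """Read a per-run response table (columns experiment + response names)."""
    df = pd.read_csv(path)
    if "experiment" not in df.columns:
        raise ValueError(f"{path}: missing 'experiment' column")
    return df


def write_responses(responses: pd.DataFrame, path: PathLike) -> None:
    responses.to_csv(path, index=False)


def params_to_dict(
    params: Union[GordonTaylorParams, ChenParams],
) -> dict[str, float]:
    """Flatten a parameter set to the canonical key-value form."""
    if isinstance(params, GordonTaylorParams):
        return {"tgs": params.tgs, "k": params.k, "tgw": params.tgw}
    return {
        "e": params.e,
        "b": params.b,
        "tw": params.tw,
        "beta": params.beta,
        "lambda_w": params.lambda_w,
    }


def params_from_dict(d: Mapping[str, float]) -> Union[GordonTaylorParams, ChenParams]:
    if "tgs" in d:
        return GordonTaylorParams(**{k: float(v) for k, v in d.items()})
    if "e" in d:
        return ChenParams(**{k: float(v) for k, v in d.items()})
    raise ValueError("parameter dict must contain 'tgs' (Gordon-Taylor) or 'e' (Chen)")


def write_params(params, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def read_params(path: PathLike):
    with open(path, encoding="utf-8") as fh:
        return params_from_dict(yaml.safe_load(fh))


def write_fit_result(fit: FitResult, path: PathLike) -> None:
    """Parameter config plus goodness of fit, one flat YAML document."""
    doc = params_to_dict(fit.params)
    doc.update(
        r_squared=float(fit.r_squared),
        n_obs=int(fit.n_obs),
        converged=bool(fit.converged),
        sse=float(fit.sse),
    )
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_mixture_model(model: MixtureModel, path: PathLike) -> None:
    doc = {
        "response_name": model.response_name,
        "terms": model.as_dict(),
    }
    if model.anova is not None:
        doc["anova"] = {
            "p_value": model.anova.p_value,
            "r_squared": model.anova.r_squared,
            "sd": model.anova.sd,
            "cv_percent": model.anova.cv_percent,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_mixture_model(path: PathLike) -> MixtureModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    anova = None
    if "anova" in doc:
        a = doc["anova"]
        p = a["p_value"]
        if isinstance(p, str):  # printed tables censor small p as '<0.0001'
            p = float(_clean(p).lstrip("<"))
        anova = AnovaStats(
            p_value=float(p),
            r_squared=float(a["r_squared"]),
            sd=float(a["sd"]),
            cv_percent=float(a["cv_percent"]),
        )
    terms = tuple(doc["terms"])
    return MixtureModel(
        response_name=doc.get("response_name", "response"),
        terms=terms,
        coefficients=tuple(float(doc["terms"][t]) for t in terms),
        anova=anova,
    )


def write_curve_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False)
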