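"""Delimited-text I/O for time series, fit results and profiles.

Time series travel as comma-separated text with the header
``time_h,value,replicate``; several replicates share one file.  Fit
results serialise as key-value lines behind a schema-version header so
downstream tooling can detect format drift.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult, InputError, TimeSeries
from .pk_simulation import PlasmaProfile

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_fit_result",
    "read_fit_result",
    "write_profile",
]

FIT_SCHEMA_VERSION = 1


def write_timeseries(series: Sequence[TimeSeries], path: str | Path) -> None:
    """Write one or more replicate series to a CSV file."""
    frames = []
    for i, ts in enumerate(series):
        frames.append(
            pd.DataFrame(
                {
                    "time_h": ts.times,
                    "value": ts.values,
                    "replicate": ts.replicate_id or f"r{i + 1}",
                    "kind": ts.kind,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_timeseries(path: str | Path, kind: str | None = None) -> list[TimeSeries]:
    """Read replicate series from CSV (columns time_h, value, optional
    replicate and kind).  ``kind`` overrides or supplies the series kind."""
    df = pd.read_csv(path)
    missing = {"time_h", "value"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = "r1"
    out: list[TimeSeries] = []
    for rep, grp in df.groupby("replicate", sort=False):
        k = kind or (str(grp["kind"].iloc[0]) if "kind" in grp.columns else None)
        if k is None:
            raise InputError(f"{path}: series kind not declared in file or argument")
        grp = grp.sort_values("time_h")
        out.append(
            TimeSeries(
                times=grp["time_h"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                kind=k,
                replicate_id=str(rep),
            )
        )
    return out


def write_fit_result(fit: FitResult, path: str | Path) -> None:
    lines = [f"schema_version: {FIT_SCHEMA_VERSION}"]
    lines.append(f"converged: {str(fit.converged).lower()}")
    lines.append(f"n_obs: {fit.n_obs}")
    lines.append(f"objective: {fit.objective!r}")
    for name, value in fit.estimates.items():
        lines.append(f"estimate.{name}: {value!r}")
    for name, value in fit.standard_errors.items():
        lines.append(f"se.{name}: {value!r}")
    if fit.alternate:
        for name, value in fit.alternate.items():
            lines.append(f"alternate.{name}: {value!r}")
    if fit.message:
        lines.append(f"message: {json.dumps(fit.message)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fit_result(path: str | Path) -> FitResult:
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    if int(fields.get("schema_version", -1)) != FIT_SCHEMA_VERSION:
        raise InputError(f"{path}: unsupported fit-result schema")
    estimates = {
        k.split(".", 1)[1]: float(v) for k, v in fields.items() if k.startswith("estimate.")
    }
    ses = {k.split(".", 1)[1]: float(v) for k, v in fields.items() if k.startswith("se.")}
    alt = {
        k.split(".", 1)[1]: float(v) for k, v in fields.items() if k.startswith("alternate.")
    }
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        objective=float(fields.get("objective", "nan")),
        converged=fields.get("converged") == "true",
        n_obs=int(fields.get("n_obs", 0)),
        message=json.loads(fields["message"]) if "message" in fields else "",
        alternate=alt or None,
    )


def write_profile(profile: PlasmaProfile, path: str | Path) -> None:
    """Write a simulated skin–plasma profile as a delimited table."""
    pd.DataFrame(
        {
            "time_h": profile.times,
            "conc_ng_per_mL": profile.conc_ng_per_mL,
            "A_vehicle_ug": profile.A_vehicle,
            "A_skin_ug": profile.A_skin,
            "A_central_ug": profile.A_central,
            "A_peripheral_ug": profile.A_peripheral,
            "A_eliminated_ug": profile.A_eliminated,
        }
    ).to_csv(path, index=False)
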