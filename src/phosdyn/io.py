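"""CSV/JSON interchange for traces, series and fit results.

Plain-text formats only: a decay trace is a two-column CSV
(``time_ms,counts``) with an optional JSON sidecar carrying acquisition
metadata and temperature; a temperature series is a CSV with columns
``temperature_K, tau_ms, ratio, sd`` (the latter three optional but at
least one of tau_ms/ratio required).  Numeric round-trips are lossless to
15 significant digits (written with repr-grade precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import (
    DecayFitResult,
    DecayTrace,
    TemperatureSeries,
    TransitionFitResult,
)

__all__ = [
    "write_trace", "read_trace",
    "write_series", "read_series",
    "decay_result_to_dict", "write_decay_result",
    "transition_result_to_dict", "write_transition_result",
]

_FLOAT_FMT = "%.17g"


def write_trace(trace: DecayTrace, path: str | Path,
                sidecar: bool = True) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_ms": trace.times, "counts": trace.counts})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if sidecar:
        meta = dict(trace.meta)
        if trace.temperature is not None:
            meta["temperature_K"] = float(trace.temperature)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trace(path: str | Path) -> DecayTrace:
    path = Path(path)
    df = _read_csv_checked(path, required=("time_ms", "counts"))
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    temperature = meta.get("temperature_K")
    return DecayTrace(df["time_ms"].to_numpy(), df["counts"].to_numpy(),
                      temperature=temperature, meta=meta)


def _read_csv_checked(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        if bad:
            rows = [int(i) + 2 for i in bad]  # +2: header line + 1-based
            raise ValueError(f"{path}: non-numeric cells in column '{col}' at rows {rows}")
        df[col] = vals
    return df


def write_series(series: TemperatureSeries, path: str | Path) -> None:
    path = Path(path)
    data: dict[str, Any] = {"temperature_K": series.temperatures}
    data["tau_ms"] = series.tau_avg if series.tau_avg is not None else np.nan
    data["ratio"] = series.ratio if series.ratio is not None else np.nan
    data["sd"] = series.sd if series.sd is not None else np.nan
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if series.provenance:
        path.with_suffix(".json").write_text(json.dumps(series.provenance, indent=2))


def read_series(path: str | Path) -> TemperatureSeries:
    path = Path(path)
    df = _read_csv_checked(path, required=("temperature_K",))
    temps = df["temperature_K"].to_numpy(dtype=float)
    bad = np.where(np.diff(temps) <= 0)[0]
    if bad.size:
        rows = [int(i) + 3 for i in bad]  # row of the offending (later) entry
        raise ValueError(f"{path}: temperatures not strictly increasing at rows {rows}")

    def _col(name: str):
        if name not in df.columns:
            return None
        vals = df[name].to_numpy(dtype=float)
        return None if np.all(np.isnan(vals)) else vals

    provenance: dict[str, Any] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return TemperatureSeries(temps, tau_avg=_col("tau_ms"), ratio=_col("ratio"),
                             sd=_col("sd"), provenance=provenance)


def decay_result_to_dict(res: DecayFitResult) -> dict[str, Any]:
    return {
        "amplitudes": res.mixture.amplitudes.tolist(),
        "lifetimes_ms": res.mixture.lifetimes.tolist(),
        "background": res.background,
        "reduced_chi2": res.reduced_chi2,
        "tau_avg_ms": res.tau_avg,
        "n_components": res.mixture.n,
        "n_tried": res.n_tried,
        "selection_trace": res.selection_trace,
        "converged": res.converged,
    }


def write_decay_result(res: DecayFitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(decay_result_to_dict(res), indent=2))


def transition_result_to_dict(res: TransitionFitResult) -> dict[str, Any]:
    return {
        "delta_E_kJ_mol": res.params.delta_E,
        "delta_S_J_mol_K": res.params.delta_S,
        "K_d": res.params.K_d,
        "tau0_ms": res.params.tau0,
        "T_MP_K": res.T_MP,
        "sd": {**res.sd, "T_MP": res.T_MP_sd},
        "reduced_chi2": res.reduced_chi2,
        "residuals": res.residuals.tolist(),
        "n_points": res.n_points,
        "converged": res.converged,
        "method": res.method_meta,
    }


def write_transition_result(res: TransitionFitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(transition_result_to_dict(res), indent=2))
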