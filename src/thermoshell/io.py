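"""Readers and writers for the package's plain-text dialects.

DSC traces: CSV with header ``temperature_C,cp_excess_kJ_per_K_mol``;
ITC heats: CSV with header ``injection,heat_uJ`` plus a TOML/JSON sidecar
for the schedule; histograms: two-column TSV; reports: versioned JSON.
Temperatures are Celsius in files, Kelvin in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .dsc import DSCTrace
from .itc import TitrationData, TitrationSchedule

REPORT_SCHEMA_VERSION = 1

__all__ = [
    "read_dsc_csv", "write_dsc_csv",
    "read_itc_csv", "write_itc_csv",
    "read_schedule", "write_schedule",
    "write_histogram_tsv", "write_report",
]


def read_dsc_csv(path, celsius: bool = True) -> DSCTrace:
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if "temperature_C" not in cols or "cp_excess_kJ_per_K_mol" not in cols:
        raise ValueError(
            "DSC CSV must have columns temperature_C,cp_excess_kJ_per_K_mol")
    t = df["temperature_C"].to_numpy(dtype=float)
    if celsius:
        t = t + 273.15
    return DSCTrace(t, df["cp_excess_kJ_per_K_mol"].to_numpy(dtype=float),
                    label=Path(path).stem)


def write_dsc_csv(trace: DSCTrace, path, celsius: bool = True) -> None:
    t = trace.temperatures - 273.15 if celsius else trace.temperatures
    df = pd.DataFrame({"temperature_C": t,
                       "cp_excess_kJ_per_K_mol": trace.cp_excess})
    df.to_csv(path, index=False, float_format="%.8g")


def read_itc_csv(path, schedule: TitrationSchedule,
                 dilution: str = "displacement") -> TitrationData:
    df = pd.read_csv(path, comment="#")
    if "injection" not in df.columns or "heat_uJ" not in df.columns:
        raise ValueError("ITC CSV must have columns injection,heat_uJ")
    df = df.sort_values("injection")
    return TitrationData(schedule, df["heat_uJ"].to_numpy(dtype=float),
                         dilution=dilution)


def write_itc_csv(data: TitrationData, path) -> None:
    df = pd.DataFrame({"injection": np.arange(1, data.heats_uJ.size + 1),
                       "heat_uJ": data.heats_uJ})
    df.to_csv(path, index=False, float_format="%.8g")


_SCHEDULE_KEYS = {
    "cell_volume_ul": "cell_volume_ul",
    "injection_volume_ul": "injection_volume_ul",
    "n_injections": "n_injections",
    "syringe_conc_M": "syringe_conc",
    "protein_conc_M": "protein_conc",
}


def read_schedule(path) -> TitrationSchedule:
    """Schedule sidecar: TOML (by suffix) or JSON, same key set."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    unknown = set(raw) - set(_SCHEDULE_KEYS)
    if unknown:
        raise ValueError(f"unknown schedule keys: {sorted(unknown)}")
    missing = set(_SCHEDULE_KEYS) - set(raw)
    if missing:
        raise ValueError(f"missing schedule keys: {sorted(missing)}")
    kwargs = {attr: raw[key] for key, attr in _SCHEDULE_KEYS.items()}
    kwargs["n_injections"] = int(kwargs["n_injections"])
    return TitrationSchedule(**kwargs)


def write_schedule(schedule: TitrationSchedule, path) -> None:
    path = Path(path)
    values = {
        "cell_volume_ul": schedule.cell_volume_ul,
        "injection_volume_ul": schedule.injection_volume_ul,
        "n_injections": schedule.n_injections,
        "syringe_conc_M": schedule.syringe_conc,
        "protein_conc_M": schedule.protein_conc,
    }
    if path.suffix == ".toml":
        lines = [f"{k} = {v}" for k, v in values.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps(values, indent=2) + "\n")


def write_histogram_tsv(path, left_column, values, header=("bin_left_A", "frequency")) -> None:
    df = pd.DataFrame({header[0]: left_column, header[1]: values})
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_report(path, payload: dict) -> None:
    """JSON report with a schema-version stamp."""
    body = {"schema_version": REPORT_SCHEMA_VERSION}
    body.update(payload)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(body, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
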