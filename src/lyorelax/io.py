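"""CSV/JSON readers and writers for the analysis pipeline.

All CSV files use one fixed dialect — UTF-8, comma separator, '.' decimal,
header required — to avoid locale drift between instrument exports.  Floats
are written with 12 significant digits so that write -> read -> write
round-trips are byte-identical.  Time-unit auto-detection is deliberately
disabled: the caller must state whether an IMC time column is seconds or
hours.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crystallization import StorageRecord
from .dsc import DSCFeatures, DSCThermogram
from .imc import PowerTimeSeries

__all__ = [
    "read_power_timeseries",
    "write_power_timeseries",
    "read_thermogram",
    "write_thermogram",
    "read_weekly_features",
    "write_weekly_features",
    "write_table",
    "write_json",
]

FLOAT_FORMAT = "%.12g"


def _read_csv(path, required_cols):
    path = Path(path)
    df = pd.read_csv(path, sep=",", encoding="utf-8")
    missing = set(required_cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing required columns {sorted(missing)}")
    for col in required_cols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based indexing
            raise ValueError(f"{path.name}: malformed value in column {col!r} at line {bad[0] + 2}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_power_timeseries(path, *, time_unit: str, **meta) -> PowerTimeSeries:
    """Read an IMC record from CSV with columns ``time_s`` (or ``time_h``)
    and ``power_uW_per_g``.  ``time_unit`` must be ``"s"`` or ``"h"``;
    there is no auto-detection.  Extra keyword arguments become record
    metadata (sample_id, process_label, ...)."""
    if time_unit not in ("s", "h"):
        raise ValueError("time_unit must be 's' or 'h' (explicit, never auto-detected)")
    time_col = f"time_{time_unit}"
    df = _read_csv(path, [time_col, "power_uW_per_g"])
    t = df[time_col].to_numpy(dtype=float)
    if t.size > 1:
        dec = np.where(np.diff(t) <= 0)[0]
        if dec.size:
            raise ValueError(
                f"{Path(path).name}: times not strictly increasing at line {dec[0] + 3}"
            )
    times_h = t / 3600.0 if time_unit == "s" else t
    return PowerTimeSeries(times=times_h, powers=df["power_uW_per_g"].to_numpy(dtype=float), **meta)


def write_power_timeseries(series: PowerTimeSeries, path, *, time_unit: str = "s") -> None:
    if time_unit not in ("s", "h"):
        raise ValueError("time_unit must be 's' or 'h'")
    t = series.times * 3600.0 if time_unit == "s" else series.times
    pd.DataFrame({f"time_{time_unit}": t, "power_uW_per_g": series.powers}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_thermogram(path, *, heating_rate: float = 2.0) -> DSCThermogram:
    df = _read_csv(path, ["temperature_C", "reversing_W_per_g", "total_W_per_g"])
    return DSCThermogram(
        temperatures=df["temperature_C"].to_numpy(dtype=float),
        reversing_signal=df["reversing_W_per_g"].to_numpy(dtype=float),
        total_signal=df["total_W_per_g"].to_numpy(dtype=float),
        heating_rate=heating_rate,
    )


def write_thermogram(thermo: DSCThermogram, path) -> None:
    pd.DataFrame(
        {
            "temperature_C": thermo.temperatures,
            "reversing_W_per_g": thermo.reversing_signal,
            "total_W_per_g": thermo.total_signal,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_weekly_features(path, *, sample_id: str = "", storage_temperature: float = 25.0) -> StorageRecord:
    """Read a weekly storage trajectory CSV with columns ``week``,
    ``time_days``, ``tg_C``, ``cryst_onset_C``, ``cryst_enthalpy_J_per_g``."""
    df = _read_csv(path, ["time_days", "cryst_enthalpy_J_per_g"])
    features = [
        DSCFeatures(
            tg_midpoint=row.get("tg_C"),
            cryst_onset=None if pd.isna(row.get("cryst_onset_C")) else float(row["cryst_onset_C"]),
            cryst_enthalpy=float(row["cryst_enthalpy_J_per_g"]),
        )
        for _, row in df.iterrows()
    ]
    return StorageRecord(
        sample_id=sample_id,
        storage_temperature=storage_temperature,
        weekly_times=df["time_days"].to_numpy(dtype=float),
        weekly_features=features,
    )


def write_weekly_features(record: StorageRecord, path) -> None:
    rows = [
        {
            "week": i,
            "time_days": record.weekly_times[i],
            "tg_C": f.tg_midpoint,
            "cryst_onset_C": f.cryst_onset,
            "cryst_enthalpy_J_per_g": f.cryst_enthalpy,
        }
        for i, f in enumerate(record.weekly_features)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_json(obj, path, *, seed=None, config=None) -> None:
    """Write a JSON artifact with provenance: tool version, seed and the
    effective configuration are embedded alongside the payload."""
    payload = {
        "tool": "lyorelax",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
        "result": _jsonable(obj),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
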