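"""CSV schemas for device exports and analysis tables.

All files are UTF-8 CSV with decimal points and ISO-8601 timestamps
carrying an explicit UTC offset (the fixed local clock of the study
site; no daylight-saving shifts).  In memory, timestamps are naive
local times.

Schemas
-------
hr2min.csv        animal_id, timestamp, hr_bpm, blank_ms
activity15.csv    animal_id, interval_start, active_minutes
ecg_manifest.csv  strip_id, animal_id, start_time, device_hr_bpm, path
<strip>.csv       t_ms, mv
temperature.csv   timestamp, temp_c
hourly_joined.csv animal_id, hour_start, hr_mean, n_hr, activity_min,
                  resting, temp_f, day_length_h, season
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .synth import EcgStrip

__all__ = [
    "DeviceExports",
    "write_hr_records",
    "read_hr_records",
    "write_activity_records",
    "read_activity_records",
    "write_temperature",
    "read_temperature",
    "write_strip",
    "read_strip",
    "write_ecg_manifest",
    "read_ecg_manifest",
    "write_hourly_joined",
    "read_hourly_joined",
    "read_device_exports",
]

log = logging.getLogger("oryxhr.io")


def _offset_str(utc_offset: float) -> str:
    sign = "+" if utc_offset >= 0 else "-"
    h = int(abs(utc_offset))
    m = int(round((abs(utc_offset) - h) * 60))
    return f"{sign}{h:02d}:{m:02d}"


def format_timestamps(ts: pd.Series, utc_offset: float) -> pd.Series:
    """Naive local timestamps -> ISO-8601 strings with explicit offset."""
    return pd.to_datetime(ts).dt.strftime("%Y-%m-%dT%H:%M:%S") + _offset_str(utc_offset)


def parse_timestamps(values: pd.Series) -> pd.Series:
    """ISO-8601 strings (offset optional) -> naive local timestamps.

    Unparseable entries become NaT (callers log and count them).
    """
    parsed = pd.to_datetime(values, errors="coerce", utc=False, format="ISO8601")
    try:
        return parsed.dt.tz_localize(None)
    except (TypeError, AttributeError):
        return parsed


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column '{c}'")


def _drop_bad_rows(df: pd.DataFrame, bad_mask: np.ndarray, path, reason: str):
    n_bad = int(bad_mask.sum())
    if n_bad:
        # +2: 1-based line numbers, header on line 1
        lines = (np.flatnonzero(bad_mask) + 2).tolist()
        log.warning("%s: rejected %d row(s) (%s) at lines %s",
                    path, n_bad, reason, lines[:20])
    return df[~bad_mask].reset_index(drop=True), n_bad


# -- 2-min heart rate -------------------------------------------------------

def write_hr_records(df: pd.DataFrame, path, utc_offset: float = -5.0) -> None:
    out = pd.DataFrame({
        "animal_id": df["animal_id"],
        "timestamp": format_timestamps(df["timestamp"], utc_offset),
        "hr_bpm": df["hr_bpm"],
        "blank_ms": df["blank_ms"],
    })
    out.to_csv(path, index=False)


def read_hr_records(path):
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["animal_id", "timestamp", "hr_bpm", "blank_ms"], path)
    ts = parse_timestamps(df["timestamp"])
    hr = pd.to_numeric(df["hr_bpm"], errors="coerce")
    blank = pd.to_numeric(df["blank_ms"], errors="coerce")
    out = pd.DataFrame({"animal_id": df["animal_id"], "timestamp": ts,
                        "hr_bpm": hr, "blank_ms": blank})
    bad = ts.isna().to_numpy() | hr.isna().to_numpy() | blank.isna().to_numpy()
    out, n_bad = _drop_bad_rows(out, bad, path, "unparseable timestamp or number")
    out["blank_ms"] = out["blank_ms"].astype(int)
    return out, n_bad


# -- 15-min activity --------------------------------------------------------

def write_activity_records(df: pd.DataFrame, path, utc_offset: float = -5.0) -> None:
    out = pd.DataFrame({
        "animal_id": df["animal_id"],
        "interval_start": format_timestamps(df["interval_start"], utc_offset),
        "active_minutes": df["active_minutes"],
    })
    out.to_csv(path, index=False)


def read_activity_records(path):
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["animal_id", "interval_start", "active_minutes"], path)
    ts = parse_timestamps(df["interval_start"])
    mins = pd.to_numeric(df["active_minutes"], errors="coerce")
    out = pd.DataFrame({"animal_id": df["animal_id"], "interval_start": ts,
                        "active_minutes": mins})
    bad = (ts.isna() | mins.isna() | (mins < 0) | (mins > 15)).to_numpy()
    out, n_bad = _drop_bad_rows(out, bad, path, "bad timestamp or minutes outside 0-15")
    out["active_minutes"] = out["active_minutes"].astype(int)
    return out, n_bad


# -- temperature ------------------------------------------------------------

def write_temperature(df: pd.DataFrame, path, utc_offset: float = -5.0) -> None:
    out = pd.DataFrame({
        "timestamp": format_timestamps(df["timestamp"], utc_offset),
        "temp_c": df["temp_c"],
    })
    out.to_csv(path, index=False)


def read_temperature(path):
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["timestamp", "temp_c"], path)
    ts = parse_timestamps(df["timestamp"])
    temp = pd.to_numeric(df["temp_c"], errors="coerce")
    out = pd.DataFrame({"timestamp": ts, "temp_c": temp})
    bad = (ts.isna() | temp.isna()).to_numpy()
    return _drop_bad_rows(out, bad, path, "unparseable timestamp or temperature")


# -- ECG strips -------------------------------------------------------------

def write_strip(strip: EcgStrip, path) -> None:
    t_ms = strip.time_ms()
    pd.DataFrame({"t_ms": t_ms, "mv": strip.samples}).to_csv(path, index=False)


def read_strip(path, animal_id: str = "", strip_id: str = None,
               device_observed_hr: float = None) -> EcgStrip:
    df = pd.read_csv(path)
    _require_columns(df, ["t_ms", "mv"], path)
    t = df["t_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: strip needs >= 2 samples")
    fs = 1000.0 / float(np.median(np.diff(t)))
    return EcgStrip(animal_id=animal_id, start_time=None,
                    samples=df["mv"].to_numpy(dtype=float), sampling_rate=fs,
                    strip_id=strip_id, device_observed_hr=device_observed_hr)


def write_ecg_manifest(df: pd.DataFrame, path, utc_offset: float = -5.0) -> None:
    out = df.copy()
    out["start_time"] = format_timestamps(out["start_time"], utc_offset)
    cols = ["strip_id", "animal_id", "start_time", "device_hr_bpm", "path"]
    out[cols].to_csv(path, index=False)


def read_ecg_manifest(path):
    df = pd.read_csv(path, dtype={"strip_id": str, "animal_id": str, "path": str})
    _require_columns(df, ["strip_id", "animal_id", "start_time", "device_hr_bpm", "path"], path)
    df["start_time"] = parse_timestamps(df["start_time"].astype(str))
    df["device_hr_bpm"] = pd.to_numeric(df["device_hr_bpm"], errors="coerce")
    return df, 0


# -- hourly joined table ----------------------------------------------------

_HOURLY_OUT = {"n_hr_records": "n_hr", "activity_minutes": "activity_min"}
_HOURLY_IN = {v: k for k, v in _HOURLY_OUT.items()}


def write_hourly_joined(df: pd.DataFrame, path, utc_offset: float = -5.0) -> None:
    out = df.rename(columns=_HOURLY_OUT).copy()
    out["hour_start"] = format_timestamps(out["hour_start"], utc_offset)
    cols = ["animal_id", "hour_start", "hr_mean", "n_hr", "activity_min",
            "resting", "temp_f", "day_length_h", "season"]
    out[cols].to_csv(path, index=False)


def read_hourly_joined(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["animal_id", "hour_start", "hr_mean", "n_hr",
                          "activity_min", "resting", "temp_f", "day_length_h",
                          "season"], path)
    df["hour_start"] = parse_timestamps(df["hour_start"].astype(str))
    return df.rename(columns=_HOURLY_IN)


# -- combined reader --------------------------------------------------------

@dataclass
class DeviceExports:
    """Typed device-export bundle with per-file rejection counts."""

    hr: pd.DataFrame
    activity: pd.DataFrame
    ecg_manifest: pd.DataFrame
    rejections: dict = field(default_factory=dict)


def read_device_exports(hr_path, activity_path, manifest_path=None) -> DeviceExports:
    """Read the device CSV exports; malformed rows are logged and counted."""
    hr, n_hr = read_hr_records(hr_path)
    act, n_act = read_activity_records(activity_path)
    if manifest_path is not None and Path(manifest_path).exists():
        manifest, n_man = read_ecg_manifest(manifest_path)
    else:
        manifest, n_man = pd.DataFrame(
            columns=["strip_id", "animal_id", "start_time", "device_hr_bpm", "path"]), 0
    return DeviceExports(hr=hr, activity=act, ecg_manifest=manifest,
                         rejections={"hr": n_hr, "activity": n_act, "ecg_manifest": n_man})
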