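"""Device-log preprocessing: clock correction, filtering, aggregation.

Hour bins are left-closed, right-open on the fixed local clock (no
daylight-saving shifts); records exactly on a boundary go to the later
hour.  Hours with no HR record are emitted with a missing ``hr_mean``
and are excluded from modeling downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FittingError

__all__ = [
    "DriftModel",
    "fit_clock_correction",
    "apply_clock_correction",
    "filter_hr_records",
    "aggregate_hourly",
    "daily_activity_totals",
    "MIN_BLANK_MS",
    "MIN_HR_BPM",
]

#: Filtering rules: keep blank settings >= 300 ms and HR >= 30 bpm
#: (records below 30 bpm or obtained with shorter blank intervals are
#: excluded).
MIN_BLANK_MS = 300
MIN_HR_BPM = 30.0


@dataclass(frozen=True)
class DriftModel:
    """Least-squares line mapping device time to reference time (seconds)."""

    slope: float
    intercept: float
    r_squared: float


def _to_epoch_s(times) -> np.ndarray:
    arr = pd.to_datetime(pd.Series(times))
    return arr.astype("int64").to_numpy() / 1e9


def fit_clock_correction(pairs) -> DriftModel:
    """Fit ``reference = slope * device + intercept`` from paired times.

    ``pairs`` is a sequence of (device_time, reference_time) tuples;
    entries may be timestamps or epoch seconds.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise FittingError("need >= 2 paired times to fit clock correction")
    device = [p[0] for p in pairs]
    ref = [p[1] for p in pairs]
    dev_s = _to_epoch_s(device) if not np.issubdtype(np.asarray(device).dtype, np.number) \
        else np.asarray(device, dtype=float)
    ref_s = _to_epoch_s(ref) if not np.issubdtype(np.asarray(ref).dtype, np.number) \
        else np.asarray(ref, dtype=float)
    if np.ptp(dev_s) == 0:
        raise FittingError("device times have zero variance")
    # center for numerical stability at epoch scale
    d0 = dev_s.mean()
    res = stats.linregress(dev_s - d0, ref_s)
    slope = float(res.slope)
    intercept = float(res.intercept - slope * d0)
    r2 = 1.0 if len(pairs) == 2 else float(res.rvalue ** 2)
    return DriftModel(slope=slope, intercept=intercept, r_squared=r2)


def apply_clock_correction(records: pd.DataFrame, model: DriftModel,
                           time_col: str = "timestamp") -> pd.DataFrame:
    """Map device timestamps through the fitted line (order-preserving)."""
    out = records.copy()
    if out.empty:
        return out
    dev_s = _to_epoch_s(out[time_col])
    corrected = model.slope * dev_s + model.intercept
    out[time_col] = pd.to_datetime((corrected * 1e9).round().astype("int64"))
    return out


def filter_hr_records(records: pd.DataFrame) -> pd.DataFrame:
    """Keep 2-min records with blank >= 300 ms and HR >= 30 bpm.

    Idempotent; exclusion of values *below* 30 bpm is strict, so a
    record at exactly 30 bpm is kept.
    """
    keep = (records["blank_ms"] >= MIN_BLANK_MS) & (records["hr_bpm"] >= MIN_HR_BPM)
    return records[keep].reset_index(drop=True)


def aggregate_hourly(hr_records: pd.DataFrame, activity_records: pd.DataFrame) -> pd.DataFrame:
    """Join 2-min HR and 15-min activity into the hourly analysis table.

    Returns one row per animal-hour present in either input, with
    ``hr_mean`` (arithmetic mean of the hour's 2-min averages, missing
    when the hour has none), ``n_hr_records``, ``activity_minutes``
    (sum of the hour's four 15-min values) and ``resting``
    (activity_minutes == 0).
    """
    hr = hr_records.copy()
    hr["hour_start"] = pd.to_datetime(hr["timestamp"]).dt.floor("h")
    hg = hr.groupby(["animal_id", "hour_start"])["hr_bpm"]
    hr_hour = hg.mean().to_frame("hr_mean")
    hr_hour["n_hr_records"] = hg.size()
    hr_hour = hr_hour.reset_index()

    act = activity_records.copy()
    ts = pd.to_datetime(act["interval_start"])
    # tolerate sub-second residue left by clock correction
    offset = (ts.dt.minute.astype("int64") * 60 + ts.dt.second) % 900
    misaligned = np.minimum(offset, 900 - offset) > 1
    if misaligned.any():
        warnings.warn(
            f"{int(misaligned.sum())} activity intervals not aligned to the "
            "15-min grid; assigned to their containing hour")
    act["hour_start"] = ts.dt.floor("h")
    act_hour = (act.groupby(["animal_id", "hour_start"])["active_minutes"]
                .sum().to_frame("activity_minutes").reset_index())

    out = hr_hour.merge(act_hour, on=["animal_id", "hour_start"], how="outer")
    out["n_hr_records"] = out["n_hr_records"].fillna(0).astype(int)
    out["resting"] = (out["activity_minutes"] == 0).astype("boolean")
    out.loc[out["activity_minutes"].isna(), "resting"] = pd.NA
    return out.sort_values(["animal_id", "hour_start"]).reset_index(drop=True)


def daily_activity_totals(activity_records: pd.DataFrame) -> pd.DataFrame:
    """Total active minutes per animal and calendar day (<= 1440)."""
    act = activity_records.copy()
    act["date"] = pd.to_datetime(act["interval_start"]).dt.normalize()
    out = (act.groupby(["animal_id", "date"])["active_minutes"]
           .sum().to_frame("total_minutes").reset_index())
    return out
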