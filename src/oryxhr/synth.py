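"""Synthetic device data with known ground truth.

Everything the analysis pipeline consumes can be generated here: 10-s ECG
strips with the bovid morphology that defeats automatic beat detection
(tall T waves after a long ST interval), multi-month 2-min heart-rate and
15-min activity series with circadian/seasonal/activity/temperature
structure, 30-min ambient temperature, and device clock drift.  Every
generator is deterministic given its seed and records the generating
truth so downstream stages can be tested for recovery.

The long-term generator builds, per animal and 2-min slot,

    HR = baseline_i + season + circadian + activity + temperature + AR(1)

where the season, activity and temperature components are centered over
the simulated window, so ``baseline_mean`` is the pooled mean heart rate
and all contrasts between conditions are unchanged.  Heart rate is
floored at 25 bpm so the downstream 30-bpm filter has work to do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .environment import assign_season, celsius_to_fahrenheit
from .errors import ParameterError

__all__ = [
    "EcgSynthParams",
    "EcgStrip",
    "SeriesSynthParams",
    "TempSynthParams",
    "DriftSpec",
    "generate_ecg_strip",
    "generate_hr_activity_series",
    "generate_temperature_series",
    "generate_hourly_ar1_series",
    "inject_clock_drift",
    "DEFAULT_ACTIVITY_PROFILE",
    "DEFAULT_ACTIVITY_SEASON_SCALE",
]


# ---------------------------------------------------------------------------
# ECG strips


@dataclass(frozen=True)
class EcgSynthParams:
    """Parameters of the bump-morphology ECG generator.

    QRS complexes and T waves are Gaussian bumps (amplitude in mV, width
    = Gaussian sigma in ms); ``t_delay`` is the R-peak to T-peak
    interval and models the species' long ST segment.  White noise and
    optional short high-amplitude bursts emulate electric noise.
    """

    sampling_rate: float = 256.0
    duration: float = 10.0
    rr_mean: float = 1000.0
    rr_jitter_sd: float = 20.0
    qrs_amplitude: float = 0.3
    qrs_width: float = 12.0
    t_amplitude: float = 0.2
    t_delay: float = 250.0
    t_width: float = 25.0
    noise_sd: float = 0.01
    noise_burst_rate: float = 0.0
    noise_burst_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise ParameterError("sampling_rate must be >= 100 samples/s")
        for name in ("duration", "rr_mean", "qrs_width", "t_delay", "t_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.t_delay <= self.qrs_width:
            raise ParameterError("t_delay must exceed qrs_width")
        for name in ("qrs_amplitude", "t_amplitude", "noise_sd",
                     "noise_burst_rate", "noise_burst_amplitude", "rr_jitter_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class EcgStrip:
    """A sampled voltage trace; the unit of accuracy validation."""

    animal_id: str
    start_time: Optional[pd.Timestamp]
    samples: np.ndarray  # mV
    sampling_rate: float
    true_beat_times: Optional[np.ndarray] = None  # ms offsets, synthetic only
    device_observed_hr: Optional[float] = None  # bpm
    strip_id: Optional[str] = None

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.sampling_rate * 1000.0

    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate * 1000.0


def _gauss_bumps(t_ms: np.ndarray, centers: np.ndarray, amp: float, sd: float) -> np.ndarray:
    v = np.zeros_like(t_ms)
    if amp == 0 or len(centers) == 0:
        return v
    for c in centers:
        lo = np.searchsorted(t_ms, c - 6 * sd)
        hi = np.searchsorted(t_ms, c + 6 * sd)
        seg = t_ms[lo:hi]
        v[lo:hi] += amp * np.exp(-0.5 * ((seg - c) / sd) ** 2)
    return v


def generate_ecg_strip(params: EcgSynthParams, animal_id: str = "synthetic",
                       start_time: Optional[pd.Timestamp] = None,
                       strip_id: Optional[str] = None) -> EcgStrip:
    """Generate one ECG strip as a superposition of QRS and T bumps.

    Beats start at ``rr_mean/2`` and advance by RR intervals jittered
    with a Gaussian truncated at +/-3 SD (keeps beats ordered); a T bump
    follows each beat by ``t_delay`` ms.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    total_ms = params.duration * 1000.0
    beats = []
    t = params.rr_mean / 2.0
    while t < total_ms:
        beats.append(t)
        jitter = np.clip(rng.normal(0.0, params.rr_jitter_sd),
                         -3 * params.rr_jitter_sd, 3 * params.rr_jitter_sd) \
            if params.rr_jitter_sd > 0 else 0.0
        t += params.rr_mean + jitter
    beats = np.asarray(beats)

    n = int(round(params.duration * params.sampling_rate))
    t_ms = np.arange(n) / params.sampling_rate * 1000.0
    v = _gauss_bumps(t_ms, beats, params.qrs_amplitude, params.qrs_width)
    t_centers = beats + params.t_delay
    t_centers = t_centers[t_centers < total_ms]
    v += _gauss_bumps(t_ms, t_centers, params.t_amplitude, params.t_width)
    if params.noise_sd > 0:
        v += rng.normal(0.0, params.noise_sd, size=n)
    if params.noise_burst_rate > 0 and params.noise_burst_amplitude > 0:
        n_bursts = rng.poisson(params.noise_burst_rate * params.duration)
        for tb in np.sort(rng.uniform(0.0, total_ms, size=n_bursts)):
            v += _gauss_bumps(t_ms, np.array([tb]), params.noise_burst_amplitude, 4.0)
    return EcgStrip(animal_id=animal_id, start_time=start_time, samples=v,
                    sampling_rate=params.sampling_rate, true_beat_times=beats,
                    strip_id=strip_id)


# ---------------------------------------------------------------------------
# Ambient temperature


@dataclass(frozen=True)
class TempSynthParams:
    """Seasonal + diurnal sinusoid temperature model (deg C, 30-min grid).

    Defaults emulate a mid-Atlantic foothill site: annual mean 12.5 C,
    seasonal swing +/-12 C (coldest mid-January), diurnal swing +/-6 C
    (warmest 15h00), Gaussian noise 2 C.
    """

    mean_c: float = 12.5
    seasonal_amplitude_c: float = 12.0
    diurnal_amplitude_c: float = 6.0
    coldest_doy: int = 15
    warmest_hour: float = 15.0
    noise_sd_c: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasonal_amplitude_c < 0 or self.diurnal_amplitude_c < 0 or self.noise_sd_c < 0:
            raise ParameterError("temperature amplitudes and noise_sd_c must be >= 0")


def generate_temperature_series(start_date, n_days: int,
                                params: TempSynthParams = TempSynthParams()) -> pd.DataFrame:
    """30-min ambient temperature records (48 per day), in deg C."""
    if n_days < 1:
        raise ParameterError("n_days must be >= 1")
    rng = np.random.default_rng(params.seed)
    start = pd.Timestamp(start_date)
    ts = start + pd.to_timedelta(np.arange(n_days * 48) * 30, unit="m")
    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = ts.hour.to_numpy(dtype=float) + ts.minute.to_numpy(dtype=float) / 60.0
    temp = (params.mean_c
            - params.seasonal_amplitude_c * np.cos(2 * np.pi * (doy - params.coldest_doy) / 365.0)
            + params.diurnal_amplitude_c * np.cos(2 * np.pi * (hour - params.warmest_hour) / 24.0))
    if params.noise_sd_c > 0:
        temp = temp + rng.normal(0.0, params.noise_sd_c, size=len(ts))
    return pd.DataFrame({"timestamp": ts, "temp_c": temp})


# ---------------------------------------------------------------------------
# Long-term heart rate + activity


def _default_profile() -> dict:
    # Expected active minutes per 15-min interval by hour, summer shape:
    # inactive at night, rising through the day, care routines at 08h and
    # 14h-15h, dusk peak 17h-18h.  Scaled so the summer daily total is
    # 214 min.
    shape = {0: 0.3, 1: 0.3, 2: 0.3, 3: 0.3, 4: 0.3, 5: 0.5, 6: 0.8, 7: 1.2,
             8: 1.8, 9: 1.5, 10: 1.4, 11: 1.3, 12: 1.0, 13: 1.2, 14: 1.8,
             15: 2.0, 16: 2.4, 17: 2.8, 18: 2.6, 19: 1.6, 20: 0.9, 21: 0.6,
             22: 0.4, 23: 0.3}
    total = 4.0 * sum(shape.values())
    factor = 214.0 / total
    return {h: v * factor for h, v in shape.items()}


DEFAULT_ACTIVITY_PROFILE = _default_profile()

#: Seasonal multipliers reproducing reported daily activity totals
#: (winter 60, spring 151, summer 214, fall 107 min).
DEFAULT_ACTIVITY_SEASON_SCALE = {
    "winter": 60.0 / 214.0,
    "spring": 151.0 / 214.0,
    "summer": 1.0,
    "fall": 107.0 / 214.0,
}


@dataclass(frozen=True)
class SeriesSynthParams:
    """Structure of the long-term 2-min HR / 15-min activity generator."""

    n_animals: int = 6
    baseline_mean: float = 60.3
    baseline_sd_between_animals: float = 5.0
    circadian_amplitude: float = 7.0
    circadian_peak_hour_by_season: dict = field(default_factory=lambda: {
        "winter": 16.0, "spring": 17.0, "summer": 18.0, "fall": 17.0})
    season_offsets: dict = field(default_factory=lambda: {
        "winter": 2.5, "spring": 1.5, "summer": -2.5, "fall": -1.5})
    activity_effect: float = 10.0  # bpm at a fully active hour
    temp_cold_effect: float = 2.0  # bpm added below cold_threshold
    temp_hot_effect: float = -2.0  # bpm added above hot_threshold
    cold_threshold: float = 20.0  # deg F
    hot_threshold: float = 80.0  # deg F
    noise_sd: float = 8.0  # marginal SD of the AR(1) noise, bpm
    ar1_coefficient: float = 0.7
    activity_rate_profile: dict = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_PROFILE))
    activity_season_scale: dict = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_SEASON_SCALE))
    start_date: str = "2019-03-01"
    n_days: int = 120
    latitude: float = 38.89292
    blank_setting: int = 300
    hr_floor: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not abs(self.ar1_coefficient) < 1:
            raise ParameterError("ar1_coefficient must satisfy |phi| < 1")


def _ar1(rng: np.random.Generator, n: int, phi: float, marginal_sd: float) -> np.ndarray:
    if marginal_sd == 0 or n == 0:
        return np.zeros(n)
    if phi == 0:
        return rng.normal(0.0, marginal_sd, size=n)
    innov_sd = marginal_sd * np.sqrt(1.0 - phi * phi)
    e = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, marginal_sd)
    y, _ = lfilter([1.0], [1.0, -phi], e, zi=np.array([phi * x0]))
    return y


def generate_hr_activity_series(params: SeriesSynthParams,
                                temperature: Optional[pd.DataFrame] = None):
    """Generate the 2-min HR and 15-min activity device logs.

    Parameters
    ----------
    params : SeriesSynthParams
    temperature : optional DataFrame(timestamp, temp_c) on a 30-min grid
        covering the window; generated internally (seed derived) if
        omitted.

    Returns
    -------
    (hr_df, activity_df, truth) where

    * ``hr_df`` has animal_id, timestamp, hr_bpm, blank_ms and the
      noiseless generating mean ``hr_true_mean`` (dropped when written
      as a device export);
    * ``activity_df`` has animal_id, interval_start, active_minutes;
    * ``truth`` is a JSON-serializable ledger of every generating
      coefficient, the per-animal baselines and the centering constants.
    """
    rng = np.random.default_rng(params.seed)
    start = pd.Timestamp(params.start_date)
    n_slots = params.n_days * 720  # 2-min slots
    n_int = params.n_days * 96  # 15-min intervals

    slot_ts = start + pd.to_timedelta(np.arange(n_slots) * 2, unit="m")
    int_ts = start + pd.to_timedelta(np.arange(n_int) * 15, unit="m")

    # shared deterministic structure ------------------------------------
    day_idx = np.arange(params.n_days)
    dates = start + pd.to_timedelta(day_idx, unit="D")
    season_by_day = assign_season(dates)
    slot_day = np.arange(n_slots) // 720
    int_day = np.arange(n_int) // 96
    slot_season = season_by_day[slot_day]
    int_season = season_by_day[int_day]
    slot_hour = (np.arange(n_slots) % 720) * 2.0 / 60.0
    int_hour = ((np.arange(n_int) % 96) * 15) // 60

    peak = np.array([params.circadian_peak_hour_by_season[s] for s in slot_season])
    circ = params.circadian_amplitude * np.cos(2 * np.pi * (slot_hour - peak) / 24.0)
    season_term = np.array([params.season_offsets[s] for s in slot_season])

    if temperature is None:
        temperature = generate_temperature_series(
            start, params.n_days, TempSynthParams(seed=params.seed + 1))
    temp_c = temperature["temp_c"].to_numpy()
    if len(temp_c) < params.n_days * 48:
        raise ParameterError("temperature series does not cover the window")
    slot_temp_f = celsius_to_fahrenheit(np.repeat(temp_c[:params.n_days * 48], 15)[:n_slots])
    temp_term = (params.temp_cold_effect * (slot_temp_f < params.cold_threshold)
                 + params.temp_hot_effect * (slot_temp_f > params.hot_threshold))

    # center components over the window so baseline_mean is the pooled mean
    c_season = float(season_term.mean())
    c_temp = float(temp_term.mean())
    profile = params.activity_rate_profile
    int_rate = np.array([profile[int(h)] for h in int_hour])
    int_scale = np.array([params.activity_season_scale[s] for s in int_season])
    p_active = np.clip(int_rate * int_scale / 15.0, 0.0, 1.0)
    c_activity = params.activity_effect * float((15.0 * p_active).mean()) / 15.0

    # between-animal baselines, centered so the pooled mean is calibrated
    z = rng.normal(0.0, 1.0, size=params.n_animals)
    if params.n_animals > 1:
        z = z - z.mean()
    baselines = params.baseline_mean + params.baseline_sd_between_animals * z
    animal_ids = [f"oryx{i + 1:02d}" for i in range(params.n_animals)]

    # 2-min slot -> containing 15-min interval (15 min = 7.5 slots)
    slot_interval = (np.arange(n_slots) * 2) // 15

    hr_frames, act_frames = [], []
    for i, aid in enumerate(animal_ids):
        active_min = rng.binomial(15, p_active)
        act_frac_slot = active_min[slot_interval] / 15.0
        mean_hr = (baselines[i]
                   + (season_term - c_season)
                   + circ
                   + params.activity_effect * act_frac_slot - c_activity
                   + (temp_term - c_temp))
        noise = _ar1(rng, n_slots, params.ar1_coefficient, params.noise_sd)
        hr = np.maximum(params.hr_floor, mean_hr + noise)
        hr_frames.append(pd.DataFrame({
            "animal_id": aid, "timestamp": slot_ts, "hr_bpm": hr,
            "blank_ms": params.blank_setting,
            "hr_true_mean": np.maximum(params.hr_floor, mean_hr)}))
        act_frames.append(pd.DataFrame({
            "animal_id": aid, "interval_start": int_ts, "active_minutes": active_min}))

    hr_df = pd.concat(hr_frames, ignore_index=True)
    act_df = pd.concat(act_frames, ignore_index=True)

    season_days = pd.Series(season_by_day).value_counts().to_dict()
    expected_daily = {
        s: float(4.0 * sum(min(15.0, profile[h] * params.activity_season_scale[s])
                           for h in range(24)))
        for s in params.activity_season_scale}
    truth = {
        "params": _params_to_jsonable(params),
        "baselines": {aid: float(b) for aid, b in zip(animal_ids, baselines)},
        "centering": {"season": c_season, "temperature": c_temp,
                      "activity": c_activity},
        "season_days": {str(k): int(v) for k, v in season_days.items()},
        "expected_daily_activity": expected_daily,
        "n_hr_records_per_animal": int(n_slots),
        "n_activity_records_per_animal": int(n_int),
    }
    return hr_df, act_df, truth


def _params_to_jsonable(params) -> dict:
    out = {}
    for k, v in dataclasses.asdict(params).items():
        if isinstance(v, dict):
            out[k] = {str(kk): float(vv) if isinstance(vv, (int, float)) else vv
                      for kk, vv in v.items()}
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def generate_hourly_ar1_series(n_animals: int = 6, n_days: int = 60,
                               baseline_mean: float = 60.3, baseline_sd: float = 5.0,
                               circadian_amplitude: float = 2.2,
                               circadian_peak_hour: float = 17.0,
                               ar1_coefficient: float = 0.7, noise_sd: float = 5.0,
                               start_date: str = "2019-03-01", seed: int = 0) -> pd.DataFrame:
    """Hourly HR series with AR(1) noise at the hourly grid plus a
    circadian signal — the residual-diagnostics scenario.

    Used to study what the autocorrelation function of null-model
    residuals looks like when serial dependence (AR(1)) and an
    unmodeled 24-h rhythm are both present.
    """
    rng = np.random.default_rng(seed)
    n = n_days * 24
    start = pd.Timestamp(start_date)
    ts = start + pd.to_timedelta(np.arange(n), unit="h")
    hour = ts.hour.to_numpy(dtype=float)
    circ = circadian_amplitude * np.cos(2 * np.pi * (hour - circadian_peak_hour) / 24.0)
    frames = []
    for i in range(n_animals):
        b = rng.normal(baseline_mean, baseline_sd)
        noise = _ar1(rng, n, ar1_coefficient, noise_sd)
        frames.append(pd.DataFrame({
            "animal_id": f"oryx{i + 1:02d}", "hour_start": ts,
            "hr_mean": b + circ + noise}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Clock drift


@dataclass(frozen=True)
class DriftSpec:
    """Affine device-clock error: ``device = true + offset + rate * days``."""

    rate: float = 0.0  # seconds of error per true day
    offset: float = 0.0  # seconds at series start

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rate) and np.isfinite(self.offset)):
            raise ParameterError("rate and offset must be finite")


def inject_clock_drift(records: pd.DataFrame, drift: DriftSpec,
                       time_col: str = "timestamp") -> pd.DataFrame:
    """Replace true timestamps with drifted device timestamps.

    Elapsed time is measured from the first record.  The true times are
    retained in a ``true_<time_col>`` column (the per-record truth
    ledger).
    """
    out = records.copy()
    true_ts = pd.to_datetime(out[time_col])
    t0 = true_ts.min()
    elapsed_days = (true_ts - t0).dt.total_seconds() / 86400.0
    shift = drift.offset + drift.rate * elapsed_days
    out["true_" + time_col] = true_ts
    out[time_col] = true_ts + pd.to_timedelta(shift, unit="s")
    return out
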