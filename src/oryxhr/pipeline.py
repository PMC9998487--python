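"""End-to-end pipeline: simulate -> sense -> validate -> preprocess ->
join covariates -> model -> report.

Configuration is TOML (unknown keys rejected); every stage reads and
writes CSV artifacts in an output directory so stages can be run
individually, and a run manifest (config hash, seeds, row counts)
accompanies each full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .environment import SiteSpec, assign_season, day_length, hourly_temperature
from .errors import ParameterError, PipelineError
from .model import (compare_models, fit_additive_model, partial_effect_table,
                    prepare_model_frame, residual_acf, standard_ladder)
from .preprocess import (aggregate_hourly, apply_clock_correction,
                         daily_activity_totals, filter_hr_records,
                         fit_clock_correction)
from .sensing import SenseParams, derived_hr, simulate_sensing
from .synth import (DriftSpec, EcgSynthParams, SeriesSynthParams,
                    TempSynthParams, generate_ecg_strip,
                    generate_hr_activity_series, generate_temperature_series,
                    inject_clock_drift)
from .validate import PeakParams, accuracy_summary, detect_r_peaks, expected_hr, validate_strip

log = logging.getLogger("oryxhr.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "load_config",
           "synthetic_hourly_frame",
           "stage_simulate", "stage_sense", "stage_validate",
           "stage_preprocess", "stage_model", "stage_report"]


def synthetic_hourly_frame(params: SeriesSynthParams,
                           temp_seed: int = None,
                           latitude: float = None):
    """Generate a series and carry it to the modeling frame, in memory.

    Runs generation -> filtering -> hourly aggregation -> covariate
    join (temperature, day length, season) and returns
    ``(frame, truth)`` where ``frame`` is ready for
    :func:`oryxhr.model.fit_additive_model`.
    """
    from .model import prepare_model_frame

    lat = latitude if latitude is not None else params.latitude
    temp = generate_temperature_series(
        params.start_date, params.n_days,
        TempSynthParams(seed=params.seed + 1 if temp_seed is None else temp_seed))
    hr, act, truth = generate_hr_activity_series(params, temperature=temp)
    hourly = aggregate_hourly(filter_hr_records(hr), act)
    temp_h = hourly_temperature(temp)[["hour_start", "temp_f"]]
    hourly = hourly.merge(temp_h, on="hour_start", how="left")
    dates = pd.to_datetime(hourly["hour_start"]).dt.normalize()
    hourly["day_length_h"] = day_length(lat, dates.to_numpy())
    hourly["season"] = assign_season(dates.to_numpy())
    return prepare_model_frame(hourly), truth


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters (see ``load_config`` for TOML keys)."""

    site: SiteSpec = field(default_factory=SiteSpec)
    series: dict = field(default_factory=dict)  # SeriesSynthParams overrides
    ecg: dict = field(default_factory=dict)  # EcgSynthParams overrides
    strips_per_animal: int = 10
    sensing: SenseParams = field(default_factory=SenseParams)
    peaks: PeakParams = field(default_factory=lambda: PeakParams(min_height=0.25))
    drift: DriftSpec = field(default_factory=lambda: DriftSpec(rate=2.0, offset=5.0))
    anchor_every_days: int = 7
    ladder_kwargs: dict = field(default_factory=dict)
    run_validate: bool = True
    run_model: bool = True
    seed: int = 1

    def series_params(self) -> SeriesSynthParams:
        return SeriesSynthParams(seed=self.seed, **self.series)

    def ecg_params(self, seed: int, rr_mean: float) -> EcgSynthParams:
        kw = dict(self.ecg)
        kw.update(seed=seed, rr_mean=rr_mean)
        return EcgSynthParams(**kw)


_KNOWN_SECTIONS = {"site", "series", "ecg", "sensing", "peaks", "drift", "run"}


def load_config(path, seed: int = None) -> PipelineConfig:
    """Load a TOML config; unknown sections or keys raise ParameterError."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ParameterError(f"unknown config sections: {sorted(unknown)}")

    def take(section, cls_fields):
        d = dict(raw.get(section, {}))
        bad = set(d) - set(cls_fields)
        if bad:
            raise ParameterError(f"unknown keys in [{section}]: {sorted(bad)}")
        return d

    site = SiteSpec(**take("site", {"latitude", "utc_offset"}))
    series = take("series", {f.name for f in dataclasses.fields(SeriesSynthParams)} - {"seed"})
    ecg_all = take("ecg", {f.name for f in dataclasses.fields(EcgSynthParams)}
                   | {"strips_per_animal"} - {"seed", "rr_mean"})
    strips_per_animal = ecg_all.pop("strips_per_animal", 10)
    sensing = SenseParams(**take("sensing", {"threshold", "blank"}))
    peaks_kw = take("peaks", {"min_height", "min_distance"})
    peaks = PeakParams(**peaks_kw) if peaks_kw else PeakParams(min_height=0.25)
    drift = DriftSpec(**take("drift", {"rate", "offset"}))
    run = take("run", {"validate", "model", "seed", "anchor_every_days",
                       "activity_df", "hour_df", "temp_df", "daylength_df",
                       "interaction_df"})
    ladder_kwargs = {k: run[k] for k in ("activity_df", "hour_df", "temp_df",
                                         "daylength_df", "interaction_df") if k in run}
    cfg = PipelineConfig(site=site, series=series, ecg=ecg_all,
                         strips_per_animal=strips_per_animal, sensing=sensing,
                         peaks=peaks, drift=drift,
                         anchor_every_days=run.get("anchor_every_days", 7),
                         ladder_kwargs=ladder_kwargs,
                         run_validate=run.get("validate", True),
                         run_model=run.get("model", True),
                         seed=seed if seed is not None else run.get("seed", 1))
    return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    """Generate device exports (HR, activity, temperature, ECG strips)."""
    out = Path(out)
    (out / "strips").mkdir(parents=True, exist_ok=True)
    params = cfg.series_params()
    hr, act, truth = generate_hr_activity_series(params)
    temp = generate_temperature_series(params.start_date, params.n_days)

    # device clocks drift; keep anchor pairs (download events) in the ledger
    hr_drift = inject_clock_drift(hr, cfg.drift)
    act_drift = inject_clock_drift(act, cfg.drift, time_col="interval_start")
    n_slots = params.n_days * 720
    step = cfg.anchor_every_days * 720
    idx = list(range(0, n_slots, step))
    if len(idx) < 2:
        idx.append(n_slots - 1)
    anchors = [(str(hr_drift["timestamp"].iloc[i]), str(hr_drift["true_timestamp"].iloc[i]))
               for i in idx]
    truth["drift"] = {"rate": cfg.drift.rate, "offset": cfg.drift.offset}
    truth["anchor_pairs"] = anchors

    rng = np.random.default_rng(cfg.seed + 1000)
    rows = []
    animals = sorted(hr["animal_id"].unique())
    for aid in animals:
        for j in range(cfg.strips_per_animal):
            rr = float(rng.uniform(700.0, 1400.0))
            sid = f"{aid}_s{j:03d}"
            strip = generate_ecg_strip(cfg.ecg_params(int(rng.integers(2**31)), rr),
                                       animal_id=aid, strip_id=sid)
            path = out / "strips" / f"{sid}.csv"
            oio.write_strip(strip, path)
            rows.append({"strip_id": sid, "animal_id": aid,
                         "start_time": pd.Timestamp(params.start_date) + pd.Timedelta(days=j),
                         "device_hr_bpm": np.nan, "path": str(path.name)})
    manifest = pd.DataFrame(rows)

    off = cfg.site.utc_offset
    oio.write_hr_records(hr_drift, out / "hr2min.csv", off)
    oio.write_activity_records(act_drift, out / "activity15.csv", off)
    oio.write_temperature(temp, out / "temperature.csv", off)
    oio.write_ecg_manifest(manifest, out / "ecg_manifest.csv", off)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return {"hr_rows": len(hr_drift), "activity_rows": len(act_drift),
            "temperature_rows": len(temp), "strips": len(manifest)}


@_stage("sense")
def stage_sense(cfg: PipelineConfig, out: Path) -> dict:
    """Run the sensing simulation on every strip; fill device HR."""
    out = Path(out)
    manifest, _ = oio.read_ecg_manifest(out / "ecg_manifest.csv")
    trains = []
    hrs = []
    for _, row in manifest.iterrows():
        strip = oio.read_strip(out / "strips" / row["path"], animal_id=row["animal_id"],
                               strip_id=row["strip_id"])
        train = simulate_sensing(strip, cfg.sensing)
        try:
            hrs.append(derived_hr(train))
        except Exception:
            hrs.append(np.nan)
        for t in train.sense_times:
            trains.append({"strip_id": row["strip_id"], "sense_time_ms": t})
    manifest["device_hr_bpm"] = hrs
    oio.write_ecg_manifest(manifest, out / "ecg_manifest.csv", cfg.site.utc_offset)
    pd.DataFrame(trains).to_csv(out / "sense_trains.csv", index=False)
    return {"strips_sensed": len(manifest)}


@_stage("validate")
def stage_validate(cfg: PipelineConfig, out: Path) -> dict:
    """RR-interval accuracy validation of the device heart rates."""
    out = Path(out)
    manifest, _ = oio.read_ecg_manifest(out / "ecg_manifest.csv")
    vals = []
    for _, row in manifest.dropna(subset=["device_hr_bpm"]).iterrows():
        strip = oio.read_strip(out / "strips" / row["path"], animal_id=row["animal_id"],
                               strip_id=row["strip_id"])
        beats = detect_r_peaks(strip, cfg.peaks)
        if len(beats) < 2:
            continue
        vals.append(validate_strip(row["device_hr_bpm"], expected_hr(beats),
                                   strip_ref=row["strip_id"], animal_id=row["animal_id"]))
    summary = accuracy_summary(vals)
    summary.per_animal.to_csv(out / "accuracy_summary.csv", index=False)
    pd.DataFrame([v.__dict__ for v in vals]).to_csv(out / "strip_validations.csv", index=False)
    return {"strips_validated": summary.total_validated,
            "strips_accurate": summary.total_accurate,
            "r_squared_adj": summary.r_squared_adj}


@_stage("preprocess")
def stage_preprocess(cfg: PipelineConfig, out: Path) -> dict:
    """Clock correction, filtering, hourly aggregation, covariate join."""
    out = Path(out)
    exports = oio.read_device_exports(out / "hr2min.csv", out / "activity15.csv")
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    pairs = [(pd.Timestamp(d), pd.Timestamp(t)) for d, t in truth["anchor_pairs"]]
    drift_model = fit_clock_correction(pairs)
    hr = apply_clock_correction(exports.hr, drift_model)
    act = apply_clock_correction(exports.activity, drift_model, time_col="interval_start")
    # device logs are second-resolution; drop sub-second correction residue
    hr["timestamp"] = hr["timestamp"].dt.round("s")
    act["interval_start"] = act["interval_start"].dt.round("s")
    hr = filter_hr_records(hr)
    hourly = aggregate_hourly(hr, act)

    temp, _ = oio.read_temperature(out / "temperature.csv")
    temp_h = hourly_temperature(temp)[["hour_start", "temp_f"]]
    hourly = hourly.merge(temp_h, on="hour_start", how="left")
    dates = pd.to_datetime(hourly["hour_start"]).dt.normalize()
    hourly["day_length_h"] = day_length(cfg.site.latitude, dates.to_numpy())
    hourly["season"] = assign_season(dates.to_numpy())
    oio.write_hourly_joined(hourly, out / "hourly_joined.csv", cfg.site.utc_offset)
    daily_activity_totals(exports.activity).to_csv(out / "daily_activity.csv", index=False)
    return {"hourly_rows": len(hourly), "filtered_hr_rows": len(hr),
            "drift_slope": drift_model.slope, "drift_r2": drift_model.r_squared}


@_stage("model")
def stage_model(cfg: PipelineConfig, out: Path) -> dict:
    """Fit the model ladder, export AIC table, coefficients, diagnostics."""
    out = Path(out)
    hourly = oio.read_hourly_joined(out / "hourly_joined.csv")
    frame = prepare_model_frame(hourly)
    ladder = standard_ladder(**cfg.ladder_kwargs)
    table = compare_models(frame, ladder)
    table.to_csv(out / "aic_ladder.csv", index=False)
    best_name = table.loc[~table["failed"], "model"].iloc[0]
    best_spec = next(s for s in ladder if s.name == best_name)
    fit = fit_additive_model(frame, best_spec)
    fit.coef_table.to_csv(out / "coefficients.csv", index=False)
    for term in best_spec.terms:
        if hasattr(term, "df") and not hasattr(term, "by"):
            x = frame[term.var].dropna()
            grid = np.linspace(float(x.min()), float(x.max()), 50)
            pe = partial_effect_table(fit, term.name, grid)
            pe.to_csv(out / f"partial_{term.var}.csv", index=False)
    null_fit = fit_additive_model(frame, next(s for s in ladder if s.name == "hrm0"))
    residual_acf(null_fit, max_lag=48).table.to_csv(out / "acf_null.csv", index=False)
    return {"best_model": best_name, "best_aic": float(table["aic"].iloc[0]),
            "r2_generalized": fit.r2_generalized}


@_stage("report")
def stage_report(cfg: PipelineConfig, out: Path, counts: dict) -> dict:
    """Write the run manifest: config hash, seeds, artifact row counts."""
    out = Path(out)
    cfg_ser = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_ser.encode()).hexdigest(),
        "seed": cfg.seed,
        "row_counts": {},
        "stage_outputs": counts,
    }
    for f in sorted(out.glob("*.csv")):
        with open(f) as fh:
            manifest["row_counts"][f.name] = sum(1 for _ in fh) - 1
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def run_pipeline(cfg: PipelineConfig, out) -> dict:
    """Execute every stage in order; returns the run manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    counts["simulate"] = stage_simulate(cfg, out)
    counts["sense"] = stage_sense(cfg, out)
    if cfg.run_validate:
        counts["validate"] = stage_validate(cfg, out)
    counts["preprocess"] = stage_preprocess(cfg, out)
    if cfg.run_model:
        counts["model"] = stage_model(cfg, out)
    manifest = stage_report(cfg, out, counts)
    log.info("pipeline complete: %s", out)
    return manifest
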