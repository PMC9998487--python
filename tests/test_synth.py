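"""Generators: ECG morphology, long-term series, temperature, drift."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oryxhr.errors import ParameterError
from oryxhr.synth import (DriftSpec, EcgSynthParams, SeriesSynthParams,
                          TempSynthParams, generate_ecg_strip,
                          generate_hourly_ar1_series,
                          generate_hr_activity_series,
                          generate_temperature_series, inject_clock_drift)

ZERO_OFFSETS = {"winter": 0.0, "spring": 0.0, "summer": 0.0, "fall": 0.0}


def local_maxima_above(v, height):
    idx = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > height)) + 1
    return idx


class TestEcgStrip:
    def test_qrs_only_strip_one_maximum_per_beat(self):
        p = EcgSynthParams(t_amplitude=0.0, noise_sd=0.0, rr_jitter_sd=0.0,
                           rr_mean=1000.0, duration=10.0, seed=1)
        strip = generate_ecg_strip(p)
        assert len(strip.true_beat_times) == 10
        peaks = local_maxima_above(strip.samples, 0.15)
        assert len(peaks) == 10
        peak_ms = peaks / strip.sampling_rate * 1000.0
        dt = 1000.0 / strip.sampling_rate
        assert np.all(np.abs(peak_ms - strip.true_beat_times) <= dt)

    def test_t_waves_double_the_suprathreshold_maxima(self):
        p = EcgSynthParams(t_amplitude=0.2, t_delay=250.0, noise_sd=0.0,
                           rr_jitter_sd=0.0, seed=1)
        strip = generate_ecg_strip(p)
        peaks = local_maxima_above(strip.samples, 0.15)
        assert len(peaks) == 2 * len(strip.true_beat_times)

    def test_seeded_determinism(self):
        p = EcgSynthParams(rr_mean=1000.0, rr_jitter_sd=20.0, seed=1)
        a, b = generate_ecg_strip(p), generate_ecg_strip(p)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.true_beat_times, b.true_beat_times)

    @given(seed=st.integers(0, 10_000), rr=st.floats(400.0, 2000.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_beat_times_ordered_and_in_range(self, seed, rr):
        strip = generate_ecg_strip(EcgSynthParams(rr_mean=rr, seed=seed))
        beats = strip.true_beat_times
        assert np.all(np.diff(beats) > 0)
        assert beats.min() >= 0 and beats.max() < strip.duration_ms
        assert len(strip.samples) == int(strip.sampling_rate * 10.0)

    @pytest.mark.parametrize("field,kwargs", [
        ("sampling_rate", {"sampling_rate": 50}),
        ("t_delay", {"t_delay": 5.0, "qrs_width": 12.0}),
        ("qrs_amplitude", {"qrs_amplitude": -0.1}),
        ("duration", {"duration": 0.0}),
    ])
    def test_invalid_params_name_the_field(self, field, kwargs):
        with pytest.raises(ParameterError, match=field):
            EcgSynthParams(**kwargs)


class TestHrActivitySeries:
    def test_degenerate_generator_equals_baseline(self):
        p = SeriesSynthParams(n_animals=3, n_days=2, circadian_amplitude=0.0,
                              activity_effect=0.0, season_offsets=dict(ZERO_OFFSETS),
                              temp_cold_effect=0.0, temp_hot_effect=0.0,
                              noise_sd=1e-9, ar1_coefficient=0.0, seed=2)
        hr, _, truth = generate_hr_activity_series(p)
        for aid, grp in hr.groupby("animal_id"):
            assert np.allclose(grp["hr_bpm"], truth["baselines"][aid], atol=1e-6)

    def test_noiseless_series_matches_closed_form_mean(self):
        p = SeriesSynthParams(n_animals=2, n_days=4, noise_sd=1e-12,
                              ar1_coefficient=0.0, seed=3)
        hr, _, _ = generate_hr_activity_series(p)
        assert np.allclose(hr["hr_bpm"], hr["hr_true_mean"], atol=1e-6)

    def test_activity_contrast_monte_carlo(self):
        # half the day fully active, half fully inactive; only the
        # activity effect present -> hourly contrast equals the effect
        profile = {h: (15.0 if h >= 12 else 0.0) for h in range(24)}
        p = SeriesSynthParams(n_animals=6, n_days=60, activity_effect=10.0,
                              circadian_amplitude=0.0, season_offsets=dict(ZERO_OFFSETS),
                              temp_cold_effect=0.0, temp_hot_effect=0.0,
                              noise_sd=1.0, ar1_coefficient=0.0,
                              activity_rate_profile=profile,
                              activity_season_scale={s: 1.0 for s in ZERO_OFFSETS},
                              seed=4)
        hr, act, _ = generate_hr_activity_series(p)
        hr = hr.copy()
        hr["interval_start"] = pd.to_datetime(hr["timestamp"]).dt.floor("15min")
        merged = hr.merge(act, on=["animal_id", "interval_start"])
        full = merged.loc[merged["active_minutes"] == 15, "hr_bpm"].mean()
        none = merged.loc[merged["active_minutes"] == 0, "hr_bpm"].mean()
        assert full - none == pytest.approx(10.0, abs=0.5)

    def test_pooled_mean_matches_default_baseline(self):
        hr, _, _ = generate_hr_activity_series(SeriesSynthParams(seed=5))
        assert hr["hr_bpm"].mean() == pytest.approx(60.3, abs=1.0)

    def test_record_invariants_and_cardinalities(self):
        p = SeriesSynthParams(n_animals=3, n_days=5, seed=6)
        hr, act, truth = generate_hr_activity_series(p)
        assert len(hr) == 3 * 5 * 720
        assert len(act) == 3 * 5 * 96
        assert (hr["hr_bpm"] >= 25.0).all()
        assert act["active_minutes"].between(0, 15).all()
        hr2, act2, _ = generate_hr_activity_series(p)
        pd.testing.assert_frame_equal(hr, hr2)
        pd.testing.assert_frame_equal(act, act2)

    def test_rejects_invalid_sizes(self):
        with pytest.raises(ParameterError, match="n_days"):
            SeriesSynthParams(n_days=0)
        with pytest.raises(ParameterError, match="n_animals"):
            SeriesSynthParams(n_animals=0)


class TestTemperature:
    def test_constant_when_amplitudes_zero(self):
        p = TempSynthParams(mean_c=10.0, seasonal_amplitude_c=0.0,
                            diurnal_amplitude_c=0.0, noise_sd_c=0.0)
        df = generate_temperature_series("2019-01-01", 3, p)
        assert np.allclose(df["temp_c"], 10.0)

    def test_cardinality_and_reproducibility(self):
        a = generate_temperature_series("2019-01-01", 365, TempSynthParams(seed=9))
        assert len(a) == 365 * 48
        b = generate_temperature_series("2019-01-01", 365, TempSynthParams(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestClockDrift:
    def test_zero_drift_is_identity(self):
        df = pd.DataFrame({"timestamp": pd.date_range("2019-01-01", periods=5, freq="2min")})
        out = inject_clock_drift(df, DriftSpec(rate=0.0, offset=0.0))
        assert (out["timestamp"] == out["true_timestamp"]).all()

    def test_drift_arithmetic(self):
        ts = pd.to_datetime(["2019-01-01", "2019-01-11"])  # 10 elapsed days
        out = inject_clock_drift(pd.DataFrame({"timestamp": ts}),
                                 DriftSpec(rate=2.0, offset=5.0))
        shift = (out["timestamp"] - out["true_timestamp"]).dt.total_seconds()
        assert shift.tolist() == [5.0, 25.0]


def test_hourly_ar1_series_shape_and_determinism():
    a = generate_hourly_ar1_series(n_animals=2, n_days=3, seed=11)
    b = generate_hourly_ar1_series(n_animals=2, n_days=3, seed=11)
    assert len(a) == 2 * 3 * 24
    pd.testing.assert_frame_equal(a, b)
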