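"""Clock correction, record filtering, hourly/daily aggregation."""

import numpy as np
import pandas as pd
import pytest

from oryxhr.errors import FittingError
from oryxhr.preprocess import (aggregate_hourly, apply_clock_correction,
                               daily_activity_totals, filter_hr_records,
                               fit_clock_correction)
from oryxhr.synth import (DriftSpec, SeriesSynthParams,
                          generate_hr_activity_series, inject_clock_drift)


class TestClockCorrection:
    def test_identity_pairs_give_identity_line(self):
        m = fit_clock_correction([(0.0, 0.0), (86400.0, 86400.0)])
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)

    def test_known_drift_recovers_affine_inverse(self):
        # device = true + 5 + 2*(elapsed days): slope 86400/86402
        true = np.array([0.0, 86400.0, 2 * 86400.0])
        device = true + 5.0 + 2.0 * true / 86400.0
        m = fit_clock_correction(list(zip(device, true)))
        assert m.slope == pytest.approx(86400.0 / 86402.0, rel=1e-12)
        assert m.intercept == pytest.approx(-5.0 * m.slope, rel=1e-9)
        assert m.r_squared == pytest.approx(1.0)

    def test_round_trip_on_synthetic_records_below_1ms(self):
        p = SeriesSynthParams(n_animals=1, n_days=30, seed=8)
        hr, _, _ = generate_hr_activity_series(p)
        drifted = inject_clock_drift(hr, DriftSpec(rate=2.0, offset=5.0))
        anchors = drifted.iloc[::720 * 7]  # weekly download events
        m = fit_clock_correction(list(zip(anchors["timestamp"],
                                          anchors["true_timestamp"])))
        corrected = apply_clock_correction(drifted, m)
        err_ms = (corrected["timestamp"] - drifted["true_timestamp"]) \
            .dt.total_seconds().abs().max() * 1000.0
        assert err_ms < 1.0
        assert m.r_squared > 1.0 - 1e-12

    def test_too_few_or_degenerate_pairs_rejected(self):
        with pytest.raises(FittingError):
            fit_clock_correction([(0.0, 0.0)])
        with pytest.raises(FittingError):
            fit_clock_correction([(5.0, 1.0), (5.0, 2.0)])

    def test_apply_to_empty_frame(self):
        m = fit_clock_correction([(0.0, 0.0), (100.0, 100.0)])
        out = apply_clock_correction(pd.DataFrame({"timestamp": []}), m)
        assert out.empty


class TestFilterRules:
    def test_toy_six_record_input_keeps_four(self):
        df = pd.DataFrame({
            "hr_bpm": [55.0, 29.0, 45.0, 31.0, 30.0, 188.0],
            "blank_ms": [300, 300, 150, 300, 300, 300]})
        kept = filter_hr_records(df)
        assert sorted(kept["hr_bpm"]) == [30.0, 31.0, 55.0, 188.0]

    def test_short_blank_excludes_everything(self):
        df = pd.DataFrame({"hr_bpm": [60.0, 70.0], "blank_ms": [150, 150]})
        assert filter_hr_records(df).empty

    def test_idempotent(self):
        df = pd.DataFrame({"hr_bpm": np.arange(20, 80, 5.0),
                           "blank_ms": [150, 300] * 6})
        once = filter_hr_records(df)
        pd.testing.assert_frame_equal(filter_hr_records(once), once)


class TestHourlyAggregation:
    def _hr(self, times, hrs, animal="a"):
        return pd.DataFrame({"animal_id": animal, "timestamp": pd.to_datetime(times),
                             "hr_bpm": hrs, "blank_ms": 300})

    def _act(self, times, mins, animal="a"):
        return pd.DataFrame({"animal_id": animal,
                             "interval_start": pd.to_datetime(times),
                             "active_minutes": mins})

    def test_hour_mean_and_activity_sum(self):
        hr = self._hr(["2019-01-01 05:02", "2019-01-01 05:30", "2019-01-01 05:58"],
                      [58.0, 60.0, 62.0])
        act = self._act(["2019-01-01 05:00", "2019-01-01 05:15",
                         "2019-01-01 05:30", "2019-01-01 05:45"], [5, 0, 10, 2])
        out = aggregate_hourly(hr, act)
        assert len(out) == 1
        assert out["hr_mean"].iloc[0] == pytest.approx(60.0)
        assert out["activity_minutes"].iloc[0] == 17
        assert out["resting"].iloc[0] == False  # noqa: E712

    def test_zero_activity_hour_is_resting(self):
        hr = self._hr(["2019-01-01 05:02"], [58.0])
        act = self._act(["2019-01-01 05:00"], [0])
        out = aggregate_hourly(hr, act)
        assert bool(out["resting"].iloc[0]) is True

    def test_boundary_record_goes_to_later_hour(self):
        hr = self._hr(["2019-01-01 05:59:59", "2019-01-01 06:00:00"], [50.0, 70.0])
        out = aggregate_hourly(hr, self._act([], []))
        assert out["hour_start"].dt.hour.tolist() == [5, 6]
        assert out["hr_mean"].tolist() == [50.0, 70.0]

    def test_aggregation_conserves_record_counts(self):
        p = SeriesSynthParams(n_animals=2, n_days=3, seed=9)
        hr, act, _ = generate_hr_activity_series(p)
        kept = filter_hr_records(hr)
        out = aggregate_hourly(kept, act)
        assert out["n_hr_records"].sum() == len(kept)

    def test_misaligned_activity_interval_warns(self):
        hr = self._hr(["2019-01-01 05:02"], [58.0])
        act = self._act(["2019-01-01 05:07"], [3])
        with pytest.warns(UserWarning, match="not aligned"):
            out = aggregate_hourly(hr, act)
        assert out["activity_minutes"].iloc[0] == 3

    def test_resting_hours_have_lower_heart_rate(self, full_frame_truth):
        frame, _ = full_frame_truth
        resting = frame[frame["resting"] == True]["hr_mean"].mean()  # noqa: E712
        active = frame[frame["resting"] == False]["hr_mean"].mean()  # noqa: E712
        assert resting < active


class TestDailyActivity:
    def test_full_day_caps_at_1440(self):
        times = pd.date_range("2019-01-01", periods=96, freq="15min")
        act = pd.DataFrame({"animal_id": "a", "interval_start": times,
                            "active_minutes": 15})
        out = daily_activity_totals(act)
        assert out["total_minutes"].iloc[0] == 1440

    def test_all_zero_gives_zero(self):
        times = pd.date_range("2019-01-01", periods=96, freq="15min")
        act = pd.DataFrame({"animal_id": "a", "interval_start": times,
                            "active_minutes": 0})
        assert daily_activity_totals(act)["total_minutes"].iloc[0] == 0

    def test_winter_profile_reproduces_expected_daily_total(self):
        # mid-winter window: generated totals match the ledger expectation
        p = SeriesSynthParams(n_animals=6, n_days=20, start_date="2019-01-05", seed=10)
        _, act, truth = generate_hr_activity_series(p)
        totals = daily_activity_totals(act)
        expect = truth["expected_daily_activity"]["winter"]
        assert totals["total_minutes"].mean() == pytest.approx(expect, rel=0.05)
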