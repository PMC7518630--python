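"""ENMO computation, gap cleaning, clock partition and daily profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import actimetrics as am
from actimetrics.timeseries import SECONDS_PER_DAY


def _record(ts, ax, ay, az):
    return am.TriaxialRecord(timestamps=pd.DatetimeIndex(ts), ax=ax, ay=ay, az=az)


def _uniform_ts(start, n, dt):
    return pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * dt, unit="s")


class TestComputeEnmo:
    @pytest.mark.parametrize(
        "axes, expected",
        [
            ((0.6, 0.8, 0.0), 0.0),  # unit norm minus one
            ((0.0, 0.0, 0.5), 0.0),  # norm < 1 truncates to zero
            ((0.6, 0.8, 0.5), np.sqrt(1.25) - 1.0),  # ~0.118034
        ],
    )
    def test_worked_examples(self, axes, expected):
        ts = _uniform_ts("2021-01-01", 3, 5.0)
        rec = _record(ts, *(np.full(3, v) for v in axes))
        series = am.compute_enmo(rec)
        assert series.values == pytest.approx(expected, abs=1e-9)
        assert series.dt == 5.0

    def test_nonnegative_on_random_axes(self):
        rng = np.random.default_rng(0)
        n = 500
        rec = _record(
            _uniform_ts("2021-01-01", n, 5.0),
            rng.normal(0, 0.8, n),
            rng.normal(0, 0.8, n),
            rng.normal(1, 0.3, n),
        )
        assert np.all(am.compute_enmo(rec).values >= 0)

    def test_non_uniform_grid_reports_index(self):
        ts = list(_uniform_ts("2021-01-01", 5, 5.0))
        ts[3] = ts[3] + pd.Timedelta(seconds=1)
        rec = _record(pd.DatetimeIndex(ts), *(np.ones(5),) * 3)
        with pytest.raises(am.NonUniformGridError) as err:
            am.compute_enmo(rec, dt=5.0)
        assert err.value.index == 3

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            _record(pd.DatetimeIndex([]), np.array([]), np.array([]), np.array([]))


class TestCleanRecording:
    DT = 60.0
    PER_DAY = int(SECONDS_PER_DAY / DT)

    def _three_days(self):
        ts = _uniform_ts("2021-06-01 00:00:00", 3 * self.PER_DAY, self.DT)
        return ts, np.arange(len(ts), dtype=float)

    def test_gap_free_identity(self):
        ts, v = self._three_days()
        res = am.clean_recording((ts, v), dt=self.DT)
        assert res.dropped_dates == []
        assert res.series.n == len(ts)
        np.testing.assert_array_equal(res.series.values, v)

    def test_missing_sample_drops_whole_day(self):
        ts, v = self._three_days()
        # remove one sample mid day 2
        kill = self.PER_DAY + 700
        keep = np.arange(len(ts)) != kill
        res = am.clean_recording((ts[keep], v[keep]), dt=self.DT)
        assert res.dropped_dates == [pd.Timestamp("2021-06-02").date()]
        assert res.series.n == 2 * self.PER_DAY

    def test_short_gap_free_series_unchanged(self):
        ts = _uniform_ts("2021-06-01 08:00:00", 100, self.DT)
        res = am.clean_recording((ts, np.ones(100)), dt=self.DT)
        assert res.series.n == 100
        assert res.dropped_dates == []

    def test_idempotent(self):
        ts, v = self._three_days()
        kill = self.PER_DAY + 700
        keep = np.arange(len(ts)) != kill
        once = am.clean_recording((ts[keep], v[keep]), dt=self.DT)
        twice = am.clean_recording(once.series, dt=self.DT)
        np.testing.assert_array_equal(once.series.values, twice.series.values)
        assert twice.dropped_dates == []

    def test_all_days_dropped_errors(self):
        ts = _uniform_ts("2021-06-01 00:00:00", 200, self.DT)
        keep = np.arange(200) != 100
        with pytest.raises(am.DegenerateSeriesError, match="no complete days"):
            am.clean_recording((ts[keep], np.ones(199)), dt=self.DT)


class TestClockPartition:
    def test_full_day_counts_at_5s(self):
        series = am.EnmoSeries(
            start="2021-01-01 00:00:00", dt=5.0, values=np.ones(17280)
        )
        day, night = am.clock_partition(series)
        assert day.n == 17 * 720  # 12240 daytime samples
        assert night.n == 7 * 720  # 5040 nighttime samples

    def test_all_night_window(self):
        series = am.EnmoSeries(
            start="2021-01-01 23:00:00", dt=5.0, values=np.ones(7 * 720)
        )
        with pytest.warns(am.ActimetricsWarning):
            day, night = am.clock_partition(series)
        assert day.n == 0 and night.n == series.n

    def test_conservation_and_order(self):
        rng = np.random.default_rng(1)
        series = am.EnmoSeries(
            start="2021-01-01 17:23:00", dt=300.0, values=rng.uniform(0, 1, 1000)
        )
        day, night = am.clock_partition(series)
        assert day.n + night.n == series.n
        mask = am.DayNightConfig().is_day(series.clock_seconds())
        np.testing.assert_array_equal(day.values, series.values[mask])
        np.testing.assert_array_equal(night.values, series.values[~mask])


class TestDailyProfile:
    def test_constant_series(self):
        series = am.EnmoSeries(
            start="2021-01-01", dt=300.0, values=np.full(576, 0.07)
        )
        prof = am.daily_profile(series, bin_minutes=60)
        np.testing.assert_allclose(prof["mean"], 0.07)

    def test_cosine_hourly_means_match_single_cycle(self):
        dt = 60.0
        per_day = int(SECONDS_PER_DAY / dt)
        t = np.arange(3 * per_day) * dt
        values = 0.1 + 0.05 * np.cos(2 * np.pi * t / SECONDS_PER_DAY)
        series = am.EnmoSeries(start="2021-01-01", dt=dt, values=values)
        prof = am.daily_profile(series, bin_minutes=60)
        one_cycle = values[:per_day].reshape(24, 60).mean(axis=1)
        np.testing.assert_allclose(prof["mean"], one_cycle, rtol=1e-12)

    def test_weighted_bin_means_reconstruct_overall_mean(self):
        rng = np.random.default_rng(5)
        series = am.EnmoSeries(
            start="2021-01-01 03:17:00", dt=300.0, values=rng.uniform(0, 1, 700)
        )
        prof = am.daily_profile(series, bin_minutes=30)
        ok = prof["count"] > 0
        weighted = np.sum(prof["mean"][ok] * prof["count"][ok]) / prof["count"].sum()
        assert weighted == pytest.approx(series.mean, rel=1e-12)

    def test_bin_minutes_must_divide_day(self):
        series = am.EnmoSeries(start="2021-01-01", dt=300.0, values=np.ones(10))
        with pytest.raises(ValueError):
            am.daily_profile(series, bin_minutes=7)


class TestCsvIO:
    def test_triaxial_roundtrip(self, tmp_path):
        ts = _uniform_ts("2021-01-01 00:00:00", 10, 5.0)
        df = pd.DataFrame(
            {"timestamp": ts, "x": 0.6, "y": 0.8, "z": 0.5}
        )
        path = tmp_path / "rec.csv"
        df.to_csv(path, index=False)
        rec = am.read_recording_csv(path)
        series = am.compute_enmo(rec)
        assert series.values == pytest.approx(np.sqrt(1.25) - 1.0)

    def test_enmo_dialect_roundtrip(self, tmp_path):
        series = am.EnmoSeries(
            start="2021-01-01 00:00:00", dt=5.0, values=np.linspace(0, 0.2, 20)
        )
        path = tmp_path / "enmo.csv"
        am.write_enmo_csv(series, path)
        ts, values = am.read_recording_csv(path)
        np.testing.assert_allclose(values, series.values)
        result = am.clean_recording((ts, values))
        assert result.series.dt == 5.0

    def test_drop_report_json(self, tmp_path):
        series = am.EnmoSeries(start="2021-01-01", dt=5.0, values=np.ones(5))
        res = am.CleanResult(series=series, dropped_dates=[pd.Timestamp("2021-01-02").date()])
        path = tmp_path / "drops.json"
        am.write_drop_report(res, path)
        assert path.read_text() == '["2021-01-02"]'

    def test_unknown_dialect_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="dialect"):
            am.read_recording_csv(path)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(10, 400))
def test_partition_conserves_samples_property(seed, n):
    rng = np.random.default_rng(seed)
    series = am.EnmoSeries(
        start="2021-01-01 11:00:00", dt=600.0, values=rng.uniform(0, 1, n)
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", am.ActimetricsWarning)
        day, night = am.clock_partition(series)
    assert day.n + night.n == n
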