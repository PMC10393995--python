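"""Heatwave thresholds, daily magnitudes, HMD/EPM vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_daily

from climstress.data_io import SeasonWindow, season_labels
from climstress.indices import (
    DegenerateClimatologyError,
    ThresholdClimatology,
    WindowError,
    build_threshold_climatology,
    daily_magnitude,
    detect_heatwaves,
    seasonal_epm,
    seasonal_hmd,
)
from climstress.synthetic import WeatherGenParams, generate_daily_weather


def _const_clim(t90=30.0, low=25.0, high=35.0, p95=20.0) -> ThresholdClimatology:
    days = pd.date_range("1999-10-01", "2000-02-28", freq="D")
    return ThresholdClimatology(
        t90_by_day={(d.month, d.day): t90 for d in days},
        t_norm_low=low, t_norm_high=high, p95=p95, half_window=15, n_seasons=2,
    )


def brute_force_hmd(tmax, t90, clim, min_run=3):
    """Independent oracle: scan all days, group runs, drop short, sum."""
    exceed = [t > q for t, q in zip(tmax, t90)]
    runs, cur = [], []
    for i, e in enumerate(exceed):
        if e:
            cur.append(i)
        else:
            if len(cur) >= min_run:
                runs.append(cur)
            cur = []
    if len(cur) >= min_run:
        runs.append(cur)
    hmd = sum(
        max((tmax[i] - clim.t_norm_low) / (clim.t_norm_high - clim.t_norm_low), 0.0)
        for run in runs for i in run
    )
    freq = sum(len(r) for r in runs)
    return hmd, freq


class TestThresholdClimatology:
    def test_constant_series_gives_constant_thresholds(self):
        dates = pd.date_range("1986-06-01", "1989-03-31", freq="D")
        d = make_daily(dates, 30.0, 0.0)
        clim = build_threshold_climatology(d, season_labels(1986, 2))
        assert all(v == 30.0 for v in clim.t90_by_day.values())
        assert clim.t_norm_low == clim.t_norm_high == 30.0

    def test_pooled_percentile_matches_brute_force_enumeration(self):
        # 3 seasons, half_window=1 -> each day pools exactly 9 values
        rng = np.random.default_rng(12)
        dates = pd.date_range("1986-06-01", "1990-03-31", freq="D")
        d = make_daily(dates, rng.normal(25, 5, len(dates)), 0.0)
        seasons = season_labels(1986, 3)
        clim = build_threshold_climatology(d, seasons, half_window=1)
        tser = d.tmax
        for month, day in [(10, 1), (12, 25), (2, 28), (11, 30)]:
            pool = []
            for lbl in seasons:
                y = SeasonWindow(lbl).start_year
                year = y if month >= 10 else y + 1
                c = pd.Timestamp(year, month, day)
                for off in (-1, 0, 1):
                    pool.append(tser.loc[c + pd.Timedelta(days=off)])
            assert len(pool) == 9
            np.testing.assert_allclose(
                clim.t90_by_day[(month, day)], np.percentile(pool, 90), rtol=1e-12
            )

    def test_zero_precip_gives_zero_p95(self):
        dates = pd.date_range("1986-06-01", "1989-03-31", freq="D")
        clim = build_threshold_climatology(make_daily(dates, 25.0, 0.0),
                                           season_labels(1986, 2))
        assert clim.p95 == 0.0

    def test_insufficient_padding_raises_window_error(self):
        dates = pd.date_range("1986-10-01", "1988-03-31", freq="D")
        with pytest.raises(WindowError):
            build_threshold_climatology(make_daily(dates, 25.0, 0.0),
                                        season_labels(1986, 2))

    def test_fewer_than_two_seasons_rejected(self, small_weather):
        with pytest.raises(ValueError, match="2 seasons"):
            build_threshold_climatology(small_weather, ["1986/87"])

    def test_p95_exceedance_fraction_bounded(self, study_weather, study_seasons, study_clim):
        pooled = np.concatenate(
            [study_weather.window(*SeasonWindow(l).epm_window)["precip_mm"].to_numpy()
             for l in study_seasons]
        )
        # linear interpolation can land p95 just below an order statistic:
        # allow one extra exceedance day in the pooled sample
        assert (pooled > study_clim.p95).mean() <= 0.05 + 1.0 / len(pooled)


class TestDailyMagnitude:
    def test_below_threshold_is_zero(self):
        clim = _const_clim()
        assert daily_magnitude(30.0, 30.0, clim) == 0.0
        assert daily_magnitude(20.0, 30.0, clim) == 0.0

    def test_upper_normalization_point_is_one(self):
        clim = _const_clim(t90=30.0, low=25.0, high=35.0)
        assert daily_magnitude(35.0, 30.0, clim) == 1.0

    def test_direct_substitution(self):
        clim = _const_clim(t90=35.0, low=30.0, high=34.0)
        assert daily_magnitude(38.0, 35.0, clim) == pytest.approx(2.0)

    def test_negative_magnitudes_clamped(self):
        clim = _const_clim(t90=20.0, low=25.0, high=35.0)
        assert daily_magnitude(22.0, 20.0, clim) == 0.0

    def test_degenerate_climatology_raises(self):
        clim = _const_clim(low=30.0, high=30.0)
        with pytest.raises(DegenerateClimatologyError):
            daily_magnitude(35.0, 30.0, clim)


class TestHeatwaveDetection:
    def _series(self, pattern, hot=36.0, cold=20.0):
        dates = pd.date_range("2000-10-01", periods=len(pattern), freq="D")
        return make_daily(dates, [hot if c == "h" else cold for c in pattern], 0.0)

    def test_no_exceedance_gives_empty_list(self):
        runs = detect_heatwaves(self._series("cccccc"), _const_clim())
        assert runs == []

    def test_short_runs_filtered_by_minimum_length(self):
        runs = detect_heatwaves(self._series("hhc" + "hhhc" + "hhhhh"), _const_clim())
        assert [r.length for r in runs] == [3, 5]

    def test_whole_window_exceeding_is_one_run(self):
        runs = detect_heatwaves(self._series("h" * 20), _const_clim())
        assert len(runs) == 1 and runs[0].length == 20

    def test_streaming_equals_brute_force_on_random_fixtures(self):
        clim = _const_clim(t90=30.0, low=28.0, high=33.0)
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(10, 151))
            tmax = rng.normal(29, 3, n)
            dates = pd.date_range("2000-10-01", periods=n, freq="D")
            d = make_daily(dates, tmax, 0.0)
            runs = detect_heatwaves(d, clim)
            got = seasonal_hmd(runs)
            t90 = [clim.t90(x) for x in dates]
            expected = brute_force_hmd(tmax, t90, clim)
            assert got[1] == expected[1]
            np.testing.assert_allclose(got[0], expected[0], rtol=1e-12)

    def test_hmd_monotone_in_heatwave_day_temperature(self):
        clim = _const_clim(t90=30.0, low=28.0, high=33.0)
        d = self._series("hhhhcc")
        base, _ = seasonal_hmd(detect_heatwaves(d, clim))
        hotter = d.data.copy()
        hotter.iloc[0, hotter.columns.get_loc("tmax_c")] += 1.0
        from climstress.data_io import DailySeries

        up, _ = seasonal_hmd(detect_heatwaves(DailySeries(hotter), clim))
        assert up > base


class TestSeasonalHmdEpm:
    def test_empty_runs_are_zero(self):
        assert seasonal_hmd([]) == (0.0, 0)

    def test_single_run_direct_summation(self):
        from climstress.indices import HeatwaveRun

        run = HeatwaveRun(start=pd.Timestamp("2000-12-01"), length=3,
                          magnitudes=np.array([0.5, 1.0, 0.25]))
        assert seasonal_hmd([run]) == (1.75, 3)

    def test_epm_direct_substitution(self):
        clim = _const_clim(p95=20.0)
        dates = pd.date_range("2000-10-01", periods=4, freq="D")
        d = make_daily(dates, 25.0, [25.0, 30.0, 10.0, 21.0])
        assert seasonal_epm(d, clim) == (76.0, 3)

    def test_epm_all_below_threshold_is_zero(self):
        clim = _const_clim(p95=20.0)
        dates = pd.date_range("2000-10-01", periods=5, freq="D")
        d = make_daily(dates, 25.0, [5.0, 0.0, 20.0, 1.0, 19.9])
        assert seasonal_epm(d, clim) == (0.0, 0)  # strict inequality at p95

    def test_epm_equals_filter_and_sum_oracle(self):
        clim = _const_clim(p95=12.0)
        rng = np.random.default_rng(8)
        p = rng.gamma(0.7, 9.0, 120)
        dates = pd.date_range("2000-10-01", periods=120, freq="D")
        d = make_daily(dates, 25.0, p)
        epm, freq = seasonal_epm(d, clim)
        assert freq == int((p > 12.0).sum())
        np.testing.assert_allclose(epm, p[p > 12.0].sum(), rtol=1e-12)

    def test_feb29_served_by_feb28_threshold(self, study_clim):
        assert study_clim.t90(pd.Timestamp(2016, 2, 29)) == study_clim.t90_by_day[(2, 28)]


class TestGeneratedRecordProperties:
    def test_indices_nonnegative_and_freq_consistent(self, study_weather, study_seasons, study_clim):
        from climstress.indices import season_index_table

        tab = season_index_table(study_weather, study_seasons, study_clim)
        assert (tab["hmd"] >= 0).all() and (tab["epm"] >= 0).all()
        assert (tab["hmd_freq"] >= 0).all()
        # heatwave frequency is a sum of runs each >= 3 days
        assert set(tab["hmd_freq"]) <= {0} | set(range(3, 200))
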