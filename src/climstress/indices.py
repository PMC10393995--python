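"""Growing-season heatwave and extreme-precipitation indices.

Heatwaves are runs of >= 3 consecutive days whose Tmax exceeds a
per-calendar-day 90th-percentile threshold T90, computed by pooling, for
each day d, all Tmax values inside a centred 31-day window across every
study season. The daily heatwave magnitude is

    M_d = (T_d - T25) / (T75 - T25)   if T_d > T90(d), else 0,

where T25/T75 are the 25th/75th percentiles of the per-season maxima of
daily Tmax over the study period (the HWMId normalisation). The seasonal
Heat Magnitude Day index (HMD) sums M_d over all heatwave-run days in the
Oct–Feb window; its frequency is the number of such days.

The Extreme Precipitation Modified index (EPM) sums daily precipitation on
days strictly above the study-period 95th percentile inside the Oct–Mar
window; its frequency counts those days. No run-length requirement applies
to precipitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DailySeries, SeasonWindow

__all__ = [
    "ThresholdClimatology",
    "HeatwaveRun",
    "build_threshold_climatology",
    "daily_magnitude",
    "detect_heatwaves",
    "seasonal_hmd",
    "seasonal_epm",
    "season_index_table",
]


class WindowError(ValueError):
    """Series does not cover a required date window."""


class DegenerateClimatologyError(ValueError):
    """Normalisation percentiles coincide; magnitudes undefined."""


@dataclass
class ThresholdClimatology:
    """Per-calendar-day T90 plus scalar normalisation and rain thresholds.

    ``t90_by_day`` maps (month, day) over Oct 1..Feb 28 to the pooled 90th
    percentile; Feb 29 is served by the Feb 28 threshold. ``t_norm_low`` /
    ``t_norm_high`` are the heatwave-magnitude normalisation percentiles,
    ``p95`` the extreme-precipitation threshold (mm/day).
    """

    t90_by_day: dict[tuple[int, int], float]
    t_norm_low: float
    t_norm_high: float
    p95: float
    half_window: int
    n_seasons: int

    def t90(self, date: pd.Timestamp) -> float:
        key = (date.month, date.day)
        if key == (2, 29):
            key = (2, 28)
        return self.t90_by_day[key]


def _hmd_calendar_days() -> list[tuple[int, int]]:
    # Oct 1 .. Feb 28 on a non-leap template year (151 days)
    days = pd.date_range("1999-10-01", "2000-02-28", freq="D")
    return [(d.month, d.day) for d in days]


def build_threshold_climatology(
    all_seasons: DailySeries,
    seasons: list[str],
    half_window: int = 15,
    heat_pct: float = 90.0,
    precip_pct: float = 95.0,
    norm_mode: str = "season-max",
    p95_population: str = "all-days",
) -> ThresholdClimatology:
    """Pool the study period into per-day heat and scalar rain thresholds.

    For each calendar day d in the Oct–Feb window, T90(d) is the
    ``heat_pct`` percentile of the union over seasons of the 31-day window
    centred on d (about 30 x 31 values for a 30-season record). The
    normalisation percentiles use the per-season maxima of daily Tmax in
    the Oct–Feb window (``norm_mode="season-max"``) or every pooled day
    (``"all-days"``). ``p95`` is the ``precip_pct`` percentile of daily
    precipitation over the Oct–Mar windows, either over all days (default)
    or wet days only (``p95_population="wet-days"``). Percentiles use
    linear interpolation between order statistics.
    """
    if len(seasons) < 2:
        raise ValueError("need at least 2 seasons to build a climatology")

    tmax = all_seasons.tmax
    idx = all_seasons.dates
    off = pd.Timedelta(days=half_window)

    # verify padding for every season
    for label in seasons:
        start, end = SeasonWindow(label).hmd_window
        if start - off < idx[0] or end + off > idx[-1]:
            raise WindowError(
                f"series must cover {label} Oct-Feb window plus "
                f"{half_window}-day padding on both ends"
            )

    t90_by_day: dict[tuple[int, int], float] = {}
    for month, day in _hmd_calendar_days():
        pool = []
        for label in seasons:
            y = SeasonWindow(label).start_year
            year = y if month >= 10 else y + 1
            center = pd.Timestamp(year, month, day)
            vals = tmax.loc[center - off:center + off].to_numpy(float)
            pool.append(vals)
        t90_by_day[(month, day)] = float(np.percentile(np.concatenate(pool), heat_pct))

    if norm_mode == "season-max":
        maxima = [
            float(all_seasons.window(*SeasonWindow(lbl).hmd_window)["tmax_c"].max())
            for lbl in seasons
        ]
        t_low, t_high = np.percentile(maxima, [25.0, 75.0])
    elif norm_mode == "all-days":
        pooled = np.concatenate(
            [
                all_seasons.window(*SeasonWindow(lbl).hmd_window)["tmax_c"].to_numpy(float)
                for lbl in seasons
            ]
        )
        t_low, t_high = np.percentile(pooled, [25.0, 75.0])
    else:
        raise ValueError(f"unknown norm_mode {norm_mode!r}")

    rain = np.concatenate(
        [
            all_seasons.window(*SeasonWindow(lbl).epm_window)["precip_mm"].to_numpy(float)
            for lbl in seasons
        ]
    )
    if p95_population == "wet-days":
        rain = rain[rain > 0]
        if rain.size == 0:
            rain = np.zeros(1)
    elif p95_population != "all-days":
        raise ValueError(f"unknown p95_population {p95_population!r}")
    p95 = float(np.percentile(rain, precip_pct))

    return ThresholdClimatology(
        t90_by_day=t90_by_day,
        t_norm_low=float(t_low),
        t_norm_high=float(t_high),
        p95=p95,
        half_window=half_window,
        n_seasons=len(seasons),
    )


def daily_magnitude(t_d: float, t90_d: float, clim: ThresholdClimatology) -> float:
    """Normalised heatwave magnitude of one day (0 when not above T90).

    Values below the lower normalisation percentile are clamped to 0:
    magnitudes measure stress, not cool anomalies.
    """
    if clim.t_norm_high == clim.t_norm_low:
        raise DegenerateClimatologyError("t_norm_high equals t_norm_low")
    if t_d <= t90_d:
        return 0.0
    m = (t_d - clim.t_norm_low) / (clim.t_norm_high - clim.t_norm_low)
    return max(m, 0.0)


@dataclass
class HeatwaveRun:
    """One maximal run of >= min_run consecutive days above T90."""

    start: pd.Timestamp
    length: int
    magnitudes: np.ndarray  # M_d per run day

    def __post_init__(self) -> None:
        if self.length < 1 or len(self.magnitudes) != self.length:
            raise ValueError("run length must match magnitudes")


def detect_heatwaves(
    season_series: DailySeries | pd.DataFrame,
    clim: ThresholdClimatology,
    min_run: int = 3,
) -> list[HeatwaveRun]:
    """Find maximal exceedance runs of at least ``min_run`` days.

    ``season_series`` must already be restricted to one season's Oct–Feb
    window. Runs are non-overlapping and returned in calendar order.
    """
    df = season_series.data if isinstance(season_series, DailySeries) else season_series
    dates = df.index
    t = df["tmax_c"].to_numpy(float)
    t90 = np.array([clim.t90(d) for d in dates])
    exceed = t > t90

    runs: list[HeatwaveRun] = []
    i = 0
    n = len(t)
    while i < n:
        if not exceed[i]:
            i += 1
            continue
        j = i
        while j < n and exceed[j]:
            j += 1
        if j - i >= min_run:
            mags = np.array(
                [daily_magnitude(t[k], t90[k], clim) for k in range(i, j)]
            )
            runs.append(HeatwaveRun(start=dates[i], length=j - i, magnitudes=mags))
        i = j
    return runs


def seasonal_hmd(runs: list[HeatwaveRun]) -> tuple[float, int]:
    """Sum run-day magnitudes (HMD) and run lengths (heatwave-day count)."""
    hmd = float(sum(r.magnitudes.sum() for r in runs))
    freq = int(sum(r.length for r in runs))
    return hmd, freq


def seasonal_epm(
    season_series: DailySeries | pd.DataFrame, clim: ThresholdClimatology
) -> tuple[float, int]:
    """Sum precipitation on days strictly above p95 within the Oct–Mar window."""
    df = season_series.data if isinstance(season_series, DailySeries) else season_series
    p = df["precip_mm"].to_numpy(float)
    mask = p > clim.p95
    return float(p[mask].sum()), int(mask.sum())


def season_index_table(
    daily: DailySeries,
    seasons: list[str],
    clim: ThresholdClimatology,
    spei_seasonal: pd.Series | None = None,
    min_run: int = 3,
) -> pd.DataFrame:
    """Per-season HMD, heatwave frequency, EPM, extreme-rain frequency, SPEI.

    Rows are indexed by season label. ``spei_seasonal`` (label -> value) is
    attached when given, NaN otherwise.
    """
    rows = []
    for label in seasons:
        win = SeasonWindow(label)
        hmd_df = daily.window(*win.hmd_window)
        runs = detect_heatwaves(hmd_df, clim, min_run=min_run)
        hmd, hmd_freq = seasonal_hmd(runs)
        epm_df = daily.window(*win.epm_window)
        epm, epm_freq = seasonal_epm(epm_df, clim)
        spei = float(spei_seasonal.loc[label]) if spei_seasonal is not None else np.nan
        rows.append(
            {"hmd": hmd, "hmd_freq": hmd_freq, "epm": epm, "epm_freq": epm_freq,
             "spei_seasonal": spei}
        )
    return pd.DataFrame(rows, index=pd.Index(seasons, name="season_label"))
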