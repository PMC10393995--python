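"""Synthetic daily weather, monthly water balance, and seasonal yield.

Emulates the statistical structure of the study inputs — a ~30-season
Southern-Hemisphere maize record — with known ground truth so downstream
stages can be tested by parameter recovery:

* daily Tmax: annual sinusoid peaking in mid-January plus AR(1) noise plus
  injected multi-day heat events;
* daily precipitation: two-state Markov occurrence chain with
  gamma-distributed wet-day amounts plus injected extreme-rain days;
* monthly water balance: precipitation total minus a simple potential
  evapotranspiration (PET) stand-in that increases monotonically with the
  monthly mean Tmax;
* seasonal yield: smooth technology trend plus a linear combination of the
  standardized seasonal extreme indices plus Gaussian noise — the inverse of
  the combined-stress regression the analysis fits.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .data_io import DailySeries, SeasonWindow, season_labels

__all__ = [
    "WeatherGenParams",
    "YieldGenParams",
    "generate_daily_weather",
    "generate_water_balance",
    "generate_yield",
    "write_netcdf_grid",
    "write_yield_csv",
]


@dataclass(frozen=True)
class WeatherGenParams:
    """Parameters of the stochastic weather generator.

    ``precip_wet_prob`` is the dry-to-wet transition probability of the
    occurrence chain; ``precip_wet_persistence`` is the wet-to-wet
    probability. The stationary wet fraction is therefore
    p01 / (1 + p01 - p11).
    """

    n_seasons: int = 30
    start_year: int = 1986
    t_mean_annual: float = 22.0          # degC, annual-mean daily Tmax
    t_seasonal_amplitude: float = 7.0    # degC, half peak-to-trough
    t_ar1_coeff: float = 0.7             # day-to-day persistence of noise
    t_noise_sd: float = 2.5              # degC, marginal sd of AR(1) noise
    precip_wet_prob: float = 0.25        # P(wet | dry)
    precip_wet_persistence: float = 0.55  # P(wet | wet)
    precip_gamma_shape: float = 0.8
    precip_gamma_scale: float = 8.0      # mm
    heat_event_rate: float = 2.0         # events / season
    heat_event_length: float = 4.0       # mean run length, days
    heat_event_boost: float = 5.0        # degC added on event days
    rain_event_rate: float = 3.0         # events / season
    rain_event_amount: float = 40.0      # mm added on an event day
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seasons < 2:
            raise ValueError("n_seasons must be >= 2")
        for name in ("t_noise_sd", "precip_gamma_shape", "precip_gamma_scale",
                     "heat_event_rate", "heat_event_length", "heat_event_boost",
                     "rain_event_rate", "rain_event_amount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("precip_wet_prob", "precip_wet_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not abs(self.t_ar1_coeff) < 1:
            raise ValueError("|t_ar1_coeff| must be < 1")


@dataclass(frozen=True)
class YieldGenParams:
    """Ground-truth coefficients and trend for the yield generator."""

    alpha_true: float = -0.3   # heat stress
    beta_true: float = 0.6     # drought (SPEI; positive: wetter -> higher yield)
    gamma_true: float = 0.3    # excess water
    trend_kind: str = "linear"  # {linear, logistic, none}
    trend_magnitude: float = 2.0  # t/ha gained over the record
    base_yield: float = 3.0    # t/ha at the start of the record
    noise_sd: float = 0.4      # t/ha
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.trend_kind not in ("linear", "logistic", "none"):
            raise ValueError(f"unknown trend_kind {self.trend_kind!r}")


_PEAK_DOY = 15.0  # mid-January: Southern-Hemisphere Tmax maximum


def _sinusoid(dates: pd.DatetimeIndex, mean: float, amplitude: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(float)
    return mean + amplitude * np.cos(2 * np.pi * (doy - _PEAK_DOY) / 365.25)


def generate_daily_weather(params: WeatherGenParams) -> DailySeries:
    """Generate one spatial unit's daily Tmax and precipitation.

    The series runs from Jun 1 of the first season's start year through
    Mar 31 after the last season — continuous months, so the monthly
    water balance and its 3-month aggregation are defined from the first
    growing season on, with ample padding for the 31-day threshold window.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    dates = pd.date_range(
        pd.Timestamp(p.start_year, 6, 1),
        pd.Timestamp(p.start_year + p.n_seasons, 3, 31),
        freq="D",
    )
    n = len(dates)

    tmax = _sinusoid(dates, p.t_mean_annual, p.t_seasonal_amplitude)
    if p.t_noise_sd > 0:
        innov_sd = p.t_noise_sd * np.sqrt(1.0 - p.t_ar1_coeff**2)
        e = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, p.t_noise_sd)
        phi = p.t_ar1_coeff
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + e[i]
        tmax = tmax + noise

    # precipitation occurrence: 2-state Markov chain started dry
    p01, p11 = p.precip_wet_prob, p.precip_wet_persistence
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    prev = False
    for i in range(n):
        prev = u[i] < (p11 if prev else p01)
        wet[i] = prev
    precip = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet and p.precip_gamma_scale > 0 and p.precip_gamma_shape > 0:
        precip[wet] = rng.gamma(p.precip_gamma_shape, p.precip_gamma_scale, size=n_wet)

    # injected events inside each season's Oct-Mar window
    pos = pd.Series(np.arange(n), index=dates)
    for label in season_labels(p.start_year, p.n_seasons):
        win = SeasonWindow(label)
        start, end = win.epm_window
        i0, i1 = int(pos.loc[start]), int(pos.loc[end])
        span = i1 - i0 + 1
        for _ in range(rng.poisson(p.heat_event_rate)):
            # lengths 1+Poisson(mean-1): mostly >=3-day heatwaves with some
            # 1-2-day negative controls that the run filter must drop
            length = 1 + rng.poisson(max(p.heat_event_length - 1.0, 0.0))
            s = i0 + rng.integers(0, max(span - length, 1))
            tmax[s:s + length] += p.heat_event_boost
        for _ in range(rng.poisson(p.rain_event_rate)):
            d = i0 + rng.integers(0, span)
            precip[d] += p.rain_event_amount

    df = pd.DataFrame({"tmax_c": tmax, "precip_mm": precip}, index=dates)
    return DailySeries(df, unit_id="synthetic")


def markov_stationary_wet_prob(p01: float, p11: float) -> float:
    """Closed-form stationary wet probability of the occurrence chain."""
    denom = 1.0 + p01 - p11
    return p01 / denom if denom > 0 else 0.0


def generate_water_balance(
    daily: DailySeries, pet_model_coeffs: tuple[float, float] = (0.5, 0.18)
) -> pd.Series:
    """Monthly climatic water balance P - PET (mm), PeriodIndex('M').

    PET stands in for a physical evapotranspiration model with a linear
    ramp in monthly mean Tmax: PET_day = a + b * Tmax_mean (floored at 0),
    scaled by the month length. Strictly increasing in Tmax when b > 0 and
    the ramp is positive. Raises on partial first/last months.
    """
    a, b = pet_model_coeffs
    dates = daily.dates
    first, last = dates[0], dates[-1]
    if first.day != 1 or last != last + pd.offsets.MonthEnd(0):
        raise ValueError("daily series must span whole months")
    months = dates.to_period("M")
    p_month = daily.precip.groupby(months).sum()
    t_month = daily.tmax.groupby(months).mean()
    ndays = pd.Series(dates, index=dates).groupby(months).size()
    pet = np.maximum(a + b * t_month.to_numpy(float), 0.0) * ndays.to_numpy(float)
    wb = p_month.to_numpy(float) - pet
    return pd.Series(wb, index=p_month.index, name="water_balance_mm")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("degenerate index series (zero variance)")
    return (x - x.mean()) / sd


def generate_yield(indices: pd.DataFrame, params: YieldGenParams) -> pd.Series:
    """Seasonal yield (t/ha) from a season index table.

    yield_s = trend(s) + alpha*std(HMD) + beta*SPEI + gamma*std(EPM) + eps.
    HMD and EPM enter standardized (as in the combined-stress regression);
    SPEI enters raw since it is standardized by construction.
    """
    required = {"hmd", "spei_seasonal", "epm"}
    missing = required - set(indices.columns)
    if missing:
        raise ValueError(f"index table missing columns: {sorted(missing)}")
    if indices[sorted(required)].isna().any().any():
        raise ValueError("index table contains missing values")
    p = params
    rng = np.random.default_rng(p.seed)
    n = len(indices)
    s = np.arange(n, dtype=float)
    if p.trend_kind == "linear":
        trend = p.base_yield + p.trend_magnitude * s / max(n - 1, 1)
    elif p.trend_kind == "logistic":
        z = (s - n / 2.0) / (n / 8.0)
        trend = p.base_yield + p.trend_magnitude / (1.0 + np.exp(-z))
    else:
        trend = np.full(n, p.base_yield)

    signal = np.zeros(n)
    if p.alpha_true != 0.0:
        signal += p.alpha_true * _standardize(indices["hmd"].to_numpy(float))
    if p.beta_true != 0.0:
        signal += p.beta_true * indices["spei_seasonal"].to_numpy(float)
    if p.gamma_true != 0.0:
        signal += p.gamma_true * _standardize(indices["epm"].to_numpy(float))
    noise = rng.normal(0.0, p.noise_sd, size=n) if p.noise_sd > 0 else 0.0
    y = trend + signal + noise
    return pd.Series(y, index=indices.index, name="yield_t_ha")


def write_netcdf_grid(series_by_cell: dict[str, DailySeries],
                      lats: np.ndarray, lons: np.ndarray, path) -> None:
    """Write per-cell daily series to a small CF NetCDF grid (classic format).

    ``series_by_cell`` keys must be "lat_lon" labels formatted to two
    decimals, matching :func:`climstress.data_io.read_gridded_climate`.
    """
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    first = next(iter(series_by_cell.values()))
    time = first.dates
    tmax = np.empty((len(time), len(lats), len(lons)))
    precip = np.empty_like(tmax)
    for i, lat in enumerate(lats):
        for j, lon in enumerate(lons):
            s = series_by_cell[f"{lat:.2f}_{lon:.2f}"]
            tmax[:, i, j] = s.tmax.to_numpy(float)
            precip[:, i, j] = s.precip.to_numpy(float)
    ds = xr.Dataset(
        {
            "tmax": (("time", "lat", "lon"), tmax, {"units": "degC"}),
            "precip": (("time", "lat", "lon"), precip, {"units": "mm/day"}),
        },
        coords={"time": time, "lat": lats, "lon": lons},
    )
    ds.to_netcdf(path, engine="scipy")


def write_yield_csv(yields: pd.Series, path) -> None:
    pd.DataFrame({"season_label": yields.index, "yield_t_ha": yields.to_numpy(float)}).to_csv(
        path, index=False
    )
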