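"""Input containers, growing-season calendars, and regional aggregation.

The analysis operates on daily maximum temperature (degC) and precipitation
(mm/day) for one spatial unit at a time (a grid cell or a region), on monthly
water-balance / SPEI series, and on one yield value per growing season.
Growing seasons follow the Southern-Hemisphere maize convention: planting in
October, maturity in March, labelled ``"YYYY/YY+1"`` (e.g. ``"1986/87"`` spans
Oct 1 1986 – Mar 31 1987).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "DailySeries",
    "RegionMask",
    "SeasonWindow",
    "season_dates",
    "season_labels",
    "read_gridded_climate",
    "read_daily_csv",
    "read_monthly_csv",
    "read_yield_csv",
    "read_region_mask",
    "aggregate_region",
]


class UnitError(ValueError):
    """Unrecognised physical units in an input file."""


class ResolutionError(ValueError):
    """Time axis is not daily."""


class MaskError(ValueError):
    """Region mask does not intersect the available cells."""


@dataclass
class DailySeries:
    """Daily Tmax (degC) and precipitation (mm/day) for one spatial unit.

    ``data`` is a DataFrame indexed by a daily DatetimeIndex with columns
    ``tmax_c`` and ``precip_mm``. Dates must be strictly increasing with no
    duplicates; precipitation must be nonnegative where present. Missing
    values are carried as NaN.
    """

    data: pd.DataFrame
    unit_id: str = "unit"

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("DailySeries requires a DatetimeIndex")
        if idx.has_duplicates or not idx.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing without duplicates")
        missing = {"tmax_c", "precip_mm"} - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        p = self.data["precip_mm"].to_numpy(float)
        if np.nanmin(p, initial=0.0) < 0:
            raise ValueError("precipitation must be nonnegative")
        t = self.data["tmax_c"].to_numpy(float)
        if np.isinf(t).any():
            raise ValueError("tmax must be finite")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def tmax(self) -> pd.Series:
        return self.data["tmax_c"]

    @property
    def precip(self) -> pd.Series:
        return self.data["precip_mm"]

    def window(self, start: pd.Timestamp, end: pd.Timestamp) -> pd.DataFrame:
        """Inclusive date slice; raises if the range is not fully covered."""
        sub = self.data.loc[start:end]
        n_expected = (pd.Timestamp(end) - pd.Timestamp(start)).days + 1
        if len(sub) != n_expected:
            raise ValueError(
                f"{self.unit_id}: window {start.date()}..{end.date()} not fully "
                f"covered ({len(sub)}/{n_expected} days)"
            )
        return sub

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False, float_format="%.4f")


@dataclass
class RegionMask:
    """Cells belonging to one region, with latitudes for cosine weighting."""

    cells: pd.DataFrame  # columns: cell_id, lat [, weight]
    region: str = "region"

    def __post_init__(self) -> None:
        if len(self.cells) == 0:
            raise MaskError("empty region mask")
        if "weight" in self.cells.columns and (self.cells["weight"] <= 0).any():
            raise MaskError("mask weights must be positive")

    def weights(self) -> pd.Series:
        w = np.cos(np.deg2rad(self.cells["lat"].to_numpy(float)))
        if "weight" in self.cells.columns:
            w = w * self.cells["weight"].to_numpy(float)
        return pd.Series(w, index=self.cells["cell_id"].to_numpy())


_LABEL_RE = re.compile(r"^(\d{4})/(\d{2})$")


def _parse_label(label: str) -> int:
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed season label {label!r}; expected 'YYYY/YY'")
    y1 = int(m.group(1))
    if (y1 + 1) % 100 != int(m.group(2)):
        raise ValueError(f"season label {label!r}: second year must follow the first")
    return y1


@dataclass(frozen=True)
class SeasonWindow:
    """Date windows of one growing season.

    The heatwave (HMD) window runs Oct 1 – last day of February; the
    extreme-precipitation (EPM) window Oct 1 – Mar 31; drought is summarised
    over the five monthly SPEI-3 values Oct..Feb. All intervals are closed.
    """

    label: str
    start_year: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_year", _parse_label(self.label))

    @property
    def hmd_window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        y = self.start_year
        feb_end = pd.Timestamp(y + 1, 2, 29) if _is_leap(y + 1) else pd.Timestamp(y + 1, 2, 28)
        return pd.Timestamp(y, 10, 1), feb_end

    @property
    def epm_window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        y = self.start_year
        return pd.Timestamp(y, 10, 1), pd.Timestamp(y + 1, 3, 31)

    @property
    def spei_months(self) -> list[pd.Period]:
        y = self.start_year
        return [pd.Period(f"{y}-10"), pd.Period(f"{y}-11"), pd.Period(f"{y}-12"),
                pd.Period(f"{y + 1}-01"), pd.Period(f"{y + 1}-02")]


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def season_dates(label: str, which: str):
    """Resolve a season label to its index-specific date window.

    ``which`` is one of ``"hmd"`` (Oct 1 – end of Feb), ``"epm"``
    (Oct 1 – Mar 31) or ``"spei"`` (the five months Oct..Feb).
    """
    win = SeasonWindow(label)
    if which == "hmd":
        return win.hmd_window
    if which == "epm":
        return win.epm_window
    if which == "spei":
        return win.spei_months
    raise ValueError(f"unknown window kind {which!r}")


def season_labels(first_start_year: int, n_seasons: int) -> list[str]:
    """Consecutive season labels, e.g. (1986, 3) -> 1986/87..1988/89."""
    return [f"{y}/{(y + 1) % 100:02d}" for y in range(first_start_year, first_start_year + n_seasons)]


# ---------------------------------------------------------------------------
# Readers


_TEMP_K_UNITS = {"k", "kelvin", "degk"}
_TEMP_C_UNITS = {"degc", "c", "celsius", "degrees_celsius", "deg_c", "degree_celsius"}
_PRECIP_MM_UNITS = {"mm", "mm/day", "mm day-1", "mm d-1", "kg m-2 day-1"}
_PRECIP_FLUX_UNITS = {"kg m-2 s-1", "mm/s"}


def _norm_units(attr: str) -> str:
    return attr.strip().lower().replace("**", "").replace("^", "")


def read_gridded_climate(path, variable_map: dict[str, str] | None = None) -> dict[str, DailySeries]:
    """Read a CF-convention gridded daily climate file into per-cell series.

    ``variable_map`` maps the logical names ``tmax``/``precip`` to the
    variable names in the file. Temperatures stored in Kelvin are converted
    to degC; precipitation fluxes in kg m-2 s-1 to mm/day. Missing values
    propagate as NaN. Non-daily time axes raise :class:`ResolutionError`.
    """
    vm = {"tmax": "tmax", "precip": "precip"}
    if variable_map:
        vm.update(variable_map)
    ds = xr.open_dataset(path)
    try:
        time = pd.DatetimeIndex(ds["time"].values)
        if len(time) > 1:
            steps = np.diff(time.values).astype("timedelta64[h]").astype(int)
            if not np.all(steps == 24):
                raise ResolutionError("time axis is not daily")
        tvar, pvar = ds[vm["tmax"]], ds[vm["precip"]]
        t_units = _norm_units(tvar.attrs.get("units", ""))
        if t_units in _TEMP_K_UNITS:
            tvals = tvar.values - 273.15
        elif t_units in _TEMP_C_UNITS:
            tvals = tvar.values.astype(float)
        else:
            raise UnitError(f"unknown temperature units {tvar.attrs.get('units')!r}")
        p_units = _norm_units(pvar.attrs.get("units", ""))
        if p_units in _PRECIP_MM_UNITS:
            pvals = pvar.values.astype(float)
        elif p_units in _PRECIP_FLUX_UNITS:
            pvals = pvar.values * 86400.0
        else:
            raise UnitError(f"unknown precipitation units {pvar.attrs.get('units')!r}")

        lats = ds["lat"].values
        lons = ds["lon"].values
        out: dict[str, DailySeries] = {}
        for i, lat in enumerate(np.atleast_1d(lats)):
            for j, lon in enumerate(np.atleast_1d(lons)):
                cell = f"{float(lat):.2f}_{float(lon):.2f}"
                df = pd.DataFrame(
                    {"tmax_c": tvals[:, i, j], "precip_mm": pvals[:, i, j]}, index=time
                )
                out[cell] = DailySeries(df, unit_id=cell)
        return out
    finally:
        ds.close()


def read_daily_csv(path, unit_id: str = "unit") -> DailySeries:
    """Read a per-region daily climate CSV (columns date, tmax_c, precip_mm)."""
    df = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    return DailySeries(df[["tmax_c", "precip_mm"]], unit_id=unit_id)


def read_monthly_csv(path, value_col: str = "value") -> pd.Series:
    """Read a monthly series CSV (columns year, month, <value>) to a
    PeriodIndex series."""
    df = pd.read_csv(path)
    idx = pd.PeriodIndex(
        [pd.Period(f"{y}-{m:02d}") for y, m in zip(df["year"], df["month"])], freq="M"
    )
    return pd.Series(df[value_col].to_numpy(float), index=idx, name=value_col)


def read_yield_csv(path) -> pd.Series:
    """Read seasonal yield (columns season_label, yield_t_ha) indexed by label."""
    df = pd.read_csv(path)
    for lbl in df["season_label"]:
        _parse_label(str(lbl))
    return pd.Series(df["yield_t_ha"].to_numpy(float), index=df["season_label"], name="yield_t_ha")


def read_region_mask(path) -> dict[str, RegionMask]:
    """Read a mask CSV (cell_id, lat, lon, region) into per-region masks."""
    df = pd.read_csv(path)
    return {
        region: RegionMask(sub[["cell_id", "lat"]].reset_index(drop=True), region=region)
        for region, sub in df.groupby("region")
    }


# ---------------------------------------------------------------------------
# Aggregation


def _cos_weighted(mat: np.ndarray, w: np.ndarray) -> np.ndarray:
    # row-wise weighted mean ignoring NaN cells
    valid = ~np.isnan(mat)
    wm = np.where(valid, w, 0.0)
    denom = wm.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.nansum(mat * wm, axis=1) / denom
    out[denom == 0] = np.nan
    return out


def aggregate_region(per_cell, mask: RegionMask, mode: str = "index-first"):
    """Cosine-latitude-weighted mean of per-cell inputs over one region.

    ``per_cell`` maps cell_id to either a :class:`DailySeries`
    (``mode="climate-first"``: average the raw climate, then compute indices
    downstream) or to a per-season index DataFrame (``mode="index-first"``,
    the default: indices computed per cell, then averaged — this preserves
    local extremes that averaging raw fields would smooth away).
    """
    w_all = mask.weights()
    cells = [c for c in w_all.index if c in per_cell]
    if len(cells) < len(w_all):
        missing = sorted(set(w_all.index) - set(cells))
        raise MaskError(f"mask cells missing from input: {missing}")
    w = w_all.loc[cells].to_numpy(float)

    if mode == "climate-first":
        frames = [per_cell[c].data for c in cells]
        idx = frames[0].index
        for f in frames[1:]:
            if not f.index.equals(idx):
                raise ValueError("cells must share the same date index")
        out = pd.DataFrame(index=idx)
        for col in ("tmax_c", "precip_mm"):
            mat = np.column_stack([f[col].to_numpy(float) for f in frames])
            out[col] = _cos_weighted(mat, w)
        return DailySeries(out, unit_id=mask.region)
    if mode == "index-first":
        frames = [per_cell[c] for c in cells]
        idx = frames[0].index
        out = pd.DataFrame(index=idx)
        for col in frames[0].columns:
            mat = np.column_stack([f[col].to_numpy(float) for f in frames])
            out[col] = _cos_weighted(mat, w)
        return out
    raise ValueError(f"unknown aggregation mode {mode!r}")
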