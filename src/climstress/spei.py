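"""SPEI: standardized precipitation–evapotranspiration index.

The monthly climatic water balance D = P - PET is aggregated over a k-month
backward window (k = 3 here), a three-parameter log-logistic distribution is
fitted per calendar month by unbiased probability-weighted moments (PWMs),
and each aggregated value is mapped through the fitted CDF and the standard
normal quantile function. Negative SPEI marks drought; the analysis
summarises the five monthly SPEI-3 values Oct..Feb into one value per
growing season.

A precomputed-SPEI path (reading a monthly SPEI series directly) bypasses
the fitting entirely; see :func:`climstress.data_io.read_monthly_csv`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

from .data_io import SeasonWindow

__all__ = [
    "LogLogisticParams",
    "SpeiParams",
    "aggregate_k_months",
    "fit_spei_params",
    "spei_transform",
    "seasonal_spei",
]

_CDF_EPS = 1e-8


class DegenerateDistributionError(ValueError):
    """Calibration sample is (near-)constant; no distribution can be fitted."""


@dataclass(frozen=True)
class LogLogisticParams:
    """Three-parameter log-logistic: shape > 0, scale > 0, location.

    CDF: F(x) = [1 + (scale / (x - location))**shape]**-1 for x > location.
    The family only accommodates positive skew; months whose aggregated
    balance is negatively skewed are fitted on the reflected sample
    (``reflected=True``), with F(x) = 1 - F_LL(-x).
    """

    shape: float
    scale: float
    location: float
    reflected: bool = False

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    def _base_cdf(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = 1.0 / (1.0 + (self.scale / (x - self.location)) ** self.shape)
        return np.where(x <= self.location, 0.0, f)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.reflected:
            return 1.0 - self._base_cdf(-x)
        return self._base_cdf(x)

    def support_lower(self) -> float:
        """Lower end of the fitted support (-inf for reflected fits)."""
        return -np.inf if self.reflected else self.location

    def support_upper(self) -> float:
        return -self.location if self.reflected else np.inf


@dataclass
class SpeiParams:
    """Per-calendar-month log-logistic fits to the aggregated water balance."""

    by_month: dict[int, LogLogisticParams]
    scale_months: int = 3


def _check_monthly(d: pd.Series) -> pd.Series:
    if not isinstance(d.index, pd.PeriodIndex) or d.index.freqstr not in ("M", "ME"):
        raise TypeError("monthly series must have a PeriodIndex with monthly frequency")
    if d.index.has_duplicates:
        raise ValueError("duplicate months")
    full = pd.period_range(d.index[0], d.index[-1], freq="M")
    if len(full) != len(d.index) or not (d.index == full).all():
        raise ValueError("months must be contiguous")
    return d


def aggregate_k_months(d: pd.Series, k: int = 3) -> pd.Series:
    """Backward rolling k-month sum; the first k-1 months are NaN."""
    if k < 1:
        raise ValueError("k must be >= 1")
    d = _check_monthly(d)
    if len(d) < k:
        raise ValueError(f"series shorter than aggregation scale k={k}")
    return d.rolling(k).sum()


def _unbiased_pwms(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased PWM estimators a_s = E[X (1-F)^s], s = 0, 1, 2.

    Computed from the ascending order statistics x_(1..n):
    a_s = (1/n) sum_i x_(i) * C(n-i, s) / C(n-1, s).
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    i = np.arange(1, n + 1, dtype=float)
    a0 = x.mean()
    a1 = np.sum(x * (n - i)) / (n * (n - 1.0))
    a2 = np.sum(x * (n - i) * (n - i - 1.0)) / (n * (n - 1.0) * (n - 2.0))
    return float(a0), float(a1), float(a2)


def _pwm_solve(x: np.ndarray) -> tuple[float, float, float]:
    w0, w1, w2 = _unbiased_pwms(x)
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0:
        raise DegenerateDistributionError("degenerate PWM configuration")
    shape = (2.0 * w1 - w0) / denom
    if shape <= 1.0:
        # shape <= 1 has no finite mean: the PWM system is inconsistent,
        # which happens when the sample skew has the wrong sign
        raise DegenerateDistributionError(
            f"fitted shape {shape:.3f} <= 1; sample skew incompatible"
        )
    g = gamma_fn(1.0 + 1.0 / shape) * gamma_fn(1.0 - 1.0 / shape)
    scale = (w0 - 2.0 * w1) * shape / g
    if scale <= 0:
        raise DegenerateDistributionError("non-positive fitted scale")
    location = w0 - scale * g
    return shape, scale, location


def fit_loglogistic_pwm(x: np.ndarray) -> LogLogisticParams:
    """Fit the 3-parameter log-logistic by unbiased PWMs.

    Near-symmetric or negatively skewed samples fall back to fitting the
    reflected sample (the log-logistic family is positively skewed only);
    the returned parameters then describe -X and the CDF is complemented.
    """
    x = np.asarray(x, float)
    if x.size < 10:
        raise ValueError("need at least 10 values to fit")
    if np.std(x) == 0:
        raise DegenerateDistributionError("constant calibration sample")
    try:
        shape, scale, location = _pwm_solve(x)
        return LogLogisticParams(shape=shape, scale=scale, location=location)
    except DegenerateDistributionError:
        shape, scale, location = _pwm_solve(-x)
        return LogLogisticParams(shape=shape, scale=scale, location=location, reflected=True)


def fit_spei_params(
    d3: pd.Series, calibration_period: tuple | None = None, scale_months: int = 3
) -> SpeiParams:
    """Fit per-calendar-month log-logistic parameters to aggregated balances.

    ``calibration_period`` is an optional (first, last) pair of
    ``pd.Period``-compatible bounds; the default calibrates on the full
    record. At least 10 values per calendar month are required (>= 20
    recommended for stable tails).
    """
    d3 = _check_monthly(d3.dropna())
    if calibration_period is not None:
        lo, hi = (pd.Period(b, freq="M") for b in calibration_period)
        d3 = d3[(d3.index >= lo) & (d3.index <= hi)]
    by_month: dict[int, LogLogisticParams] = {}
    for month, sub in d3.groupby(d3.index.month):
        by_month[int(month)] = fit_loglogistic_pwm(sub.to_numpy(float))
    if not by_month:
        raise ValueError("no calibration data")
    return SpeiParams(by_month=by_month, scale_months=scale_months)


def spei_transform(d3: pd.Series, params: SpeiParams) -> pd.Series:
    """Map aggregated balances through the fitted CDF to standard-normal SPEI.

    Values at or below the fitted support are clamped to CDF epsilon with a
    warning (SPEI ~ -5.6); NaN inputs stay NaN.
    """
    d3 = _check_monthly(d3)
    out = np.full(len(d3), np.nan)
    vals = d3.to_numpy(float)
    months = d3.index.month
    clamped = 0
    for month in np.unique(months):
        if int(month) not in params.by_month:
            if np.isfinite(vals[months == month]).any():
                raise KeyError(f"no fitted parameters for calendar month {month}")
            continue
        ll = params.by_month[int(month)]
        sel = (months == month) & np.isfinite(vals)
        f = ll.cdf(vals[sel])
        clamped += int(((f < _CDF_EPS) | (f > 1.0 - _CDF_EPS)).sum())
        f = np.clip(f, _CDF_EPS, 1.0 - _CDF_EPS)
        out[sel] = norm.ppf(f)
    if clamped:
        warnings.warn(
            f"{clamped} value(s) outside fitted support; clamped to CDF epsilon",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.Series(out, index=d3.index, name="spei")


def seasonal_spei(
    spei: pd.Series, window: SeasonWindow, mode: str = "mean"
) -> float:
    """Reduce monthly SPEI-3 to one value per growing season.

    ``mode="mean"`` (default) averages the five Oct..Feb values;
    ``mode="february"`` takes the February SPEI-3 alone (which already
    integrates Dec–Feb). Missing months raise.
    """
    months = window.spei_months
    if mode == "february":
        months = months[-1:]
    elif mode != "mean":
        raise ValueError(f"unknown seasonal mode {mode!r}")
    try:
        vals = spei.loc[months].to_numpy(float)
    except KeyError as exc:
        raise ValueError(f"season {window.label}: SPEI month missing") from exc
    if np.isnan(vals).any():
        raise ValueError(f"season {window.label}: SPEI month missing")
    return float(vals.mean())
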