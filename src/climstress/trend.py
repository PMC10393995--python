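"""Trend and serial-structure diagnostics for seasonal index series.

Monotone trends are tested with the Mann–Kendall statistic (tie-corrected
variance, +-1 continuity correction) and quantified with Sen's slope (the
median of all pairwise slopes). Serial correlation is screened with sample
ACF/PACF; an OLS linear trend and a single-break sup-F (Chow-type) test on
a mean-plus-trend model complete the toolkit. With ~30 seasons these are
the standard low-power-but-robust choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf

__all__ = [
    "TrendResult",
    "BreakpointResult",
    "mann_kendall",
    "sens_slope",
    "autocorr_screen",
    "detect_breakpoint",
    "linear_trend",
]


class SampleError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass
class TrendResult:
    S: float
    var_S: float
    Z: float
    p_two_sided: float
    sen_slope: float
    significant: bool
    alpha: float = 0.05


@dataclass
class BreakpointResult:
    break_index: int  # argmax of the F sequence, within the trimmed interior
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def _as1d(y) -> np.ndarray:
    y = np.asarray(y, float).ravel()
    if np.isnan(y).any():
        raise ValueError("missing values not allowed")
    return y


def mann_kendall(y, alpha: float = 0.05) -> TrendResult:
    """Mann–Kendall trend test with tie correction and continuity correction.

    S sums the signs of all pairwise differences y_j - y_i (i < j); under
    the null of no trend Z = (S -+ 1)/sqrt(var S) is approximately standard
    normal. Sen's slope is attached as the trend magnitude.
    """
    y = _as1d(y)
    n = len(y)
    if n < 4:
        raise SampleError("Mann-Kendall requires n >= 4")
    diff_sign = np.sign(y[None, :] - y[:, None])
    S = float(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var_S = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if S > 0:
        Z = (S - 1.0) / np.sqrt(var_S)
    elif S < 0:
        Z = (S + 1.0) / np.sqrt(var_S)
    else:
        Z = 0.0
    p = 2.0 * stats.norm.sf(abs(Z))
    return TrendResult(
        S=S, var_S=float(var_S), Z=float(Z), p_two_sided=float(p),
        sen_slope=sens_slope(y), significant=bool(p <= alpha), alpha=alpha,
    )


def sens_slope(y) -> float:
    """Median of all pairwise slopes (y_j - y_i)/(j - i), i < j."""
    y = _as1d(y)
    n = len(y)
    if n < 2:
        raise SampleError("Sen's slope requires n >= 2")
    i, j = np.triu_indices(n, k=1)
    return float(np.median((y[j] - y[i]) / (j - i)))


def autocorr_screen(y, max_lag: int = 10, alpha: float = 0.05) -> dict:
    """Sample ACF and Durbin–Levinson PACF with white-noise significance flags.

    Lags with |r| > z_{1-alpha/2}/sqrt(n) are flagged. Returns a dict with
    arrays ``acf``, ``pacf`` (lags 0..max_lag), boolean flag arrays and the
    confidence bound.
    """
    y = _as1d(y)
    n = len(y)
    if n <= max_lag + 2:
        raise SampleError(f"need n > max_lag + 2 (n={n}, max_lag={max_lag})")
    r = _sm_acf(y, nlags=max_lag, fft=False)
    phi = _sm_pacf(y, nlags=max_lag, method="ldb")
    bound = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n)
    flags_acf = np.abs(r) > bound
    flags_pacf = np.abs(phi) > bound
    flags_acf[0] = flags_pacf[0] = False  # lag 0 is identically 1
    return {
        "acf": r, "pacf": phi,
        "acf_flagged": flags_acf, "pacf_flagged": flags_pacf,
        "bound": float(bound),
    }


def _segment_rss(y: np.ndarray, t: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _supf_stats(y: np.ndarray, trim: float) -> tuple[np.ndarray, np.ndarray]:
    """Chow F statistics over all admissible single breaks of an
    intercept+trend model."""
    n = len(y)
    t = np.arange(n, dtype=float)
    rss_full = _segment_rss(y, t)
    lo = max(int(np.ceil(trim * n)), 2)
    hi = min(int(np.floor((1 - trim) * n)), n - 2)
    ks = np.arange(lo, hi + 1)
    fstats = np.empty(len(ks))
    for m, k in enumerate(ks):
        rss1 = _segment_rss(y[:k], t[:k]) + _segment_rss(y[k:], t[k:])
        denom = rss1 / (n - 4)
        fstats[m] = ((rss_full - rss1) / 2.0) / denom if denom > 0 else np.inf
    return ks, fstats


_NULL_CACHE: dict[tuple[int, float, int], np.ndarray] = {}
_NULL_SEED = 20240915  # fixed: the null distribution is data-independent


def _supf_null(n: int, trim: float, nsim: int) -> np.ndarray:
    key = (n, trim, nsim)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(_NULL_SEED)
        sims = np.empty(nsim)
        for b in range(nsim):
            _, f = _supf_stats(rng.standard_normal(n), trim)
            sims[b] = f.max()
        _NULL_CACHE[key] = np.sort(sims)
    return _NULL_CACHE[key]


def detect_breakpoint(
    y, trim: float = 0.15, alpha: float = 0.05, nsim: int = 499
) -> BreakpointResult:
    """Single-break sup-F test in a mean-plus-linear-trend model.

    Candidate breaks are restricted to the interior [trim*n, (1-trim)*n].
    The sup-F statistic is pivotal under the iid-normal null for fixed n
    and trimming, so its p-value is computed against a cached Monte-Carlo
    null distribution (``nsim`` replicates, fixed internal seed).
    """
    y = _as1d(y)
    n = len(y)
    if n < 10:
        raise SampleError("breakpoint detection requires n >= 10")
    ks, fstats = _supf_stats(y, trim)
    stat = float(fstats.max())
    k_hat = int(ks[int(np.argmax(fstats))])
    null = _supf_null(n, trim, nsim)
    p = float((np.sum(null >= stat) + 1) / (nsim + 1))
    return BreakpointResult(
        break_index=k_hat, statistic=stat, p_value=p,
        significant=bool(p <= alpha), alpha=alpha,
    )


def linear_trend(y) -> tuple[float, float, float]:
    """OLS slope, intercept and two-sided slope p-value against season index."""
    y = _as1d(y)
    n = len(y)
    if n < 3:
        raise SampleError("linear trend requires n >= 3")
    t = np.arange(n, dtype=float)
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)
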