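"""Modified Combined Stress Index: yield anomalies vs climate extremes.

Observed yield carries a slow technology trend; it is removed with a LOESS
smooth whose span is chosen by fivefold cross-validation (lowest held-out
MSE). Each extreme-index series is detrended with LOESS only when it shows
a significant monotone trend (Mann–Kendall) or a structural break;
otherwise its mean is removed. Heat (HMD) and excess-water (EPM) anomalies
are then standardized — drought (SPEI) is standardized by construction —
and the yield anomalies are regressed on the three predictors:

    CSIm_s = alpha * HMD_std + beta * SPEI + gamma * EPM_std + eps_s.

Collinearity is screened first (VIF / tolerance / condition indices); the
fit proceeds regardless, carrying the flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trend import detect_breakpoint, mann_kendall

__all__ = [
    "LoessConfig",
    "CsimFit",
    "loess_fit",
    "select_span_cv",
    "detrend_yield",
    "conditional_detrend_index",
    "standardize",
    "collinearity_diagnostics",
    "fit_csim",
]


@dataclass(frozen=True)
class LoessConfig:
    """Span grid and CV settings for LOESS smoothing (local linear,
    tricube weights)."""

    spans: tuple[float, ...] = tuple(np.round(np.arange(0.3, 1.0001, 0.05), 2))
    degree: int = 1
    cv_folds: int = 5
    seed: int = 1234

    def __post_init__(self) -> None:
        if any(s <= 0 or s > 1 for s in self.spans):
            raise ValueError("spans must lie in (0, 1]")
        if list(self.spans) != sorted(self.spans):
            raise ValueError("spans must be sorted ascending")
        if self.degree != 1:
            raise ValueError("only local-linear LOESS (degree 1) is supported")


def _loess_eval(
    t_train: np.ndarray, y_train: np.ndarray, t_eval: np.ndarray, span: float
) -> np.ndarray:
    """Local linear regression with tricube weights at arbitrary points.

    The neighbourhood holds q = ceil(span * n) training points. For
    span >= 1 (all points in every neighbourhood) the weights are uniform,
    so the smooth coincides with the global OLS line. Points outside the
    training range are predicted by the local line at the nearest
    neighbourhood (local extrapolation).
    """
    n = len(t_train)
    q = int(np.ceil(span * n))
    if q < 3:
        raise ValueError(f"span {span} too small: neighbourhood {q} < 3 points")
    q = min(q, n)
    out = np.empty(len(t_eval))
    for m, x0 in enumerate(t_eval):
        d = np.abs(t_train - x0)
        order = np.argsort(d, kind="stable")[:q]
        dq = d[order]
        if q >= n:
            w = np.ones(q)
        else:
            dmax = dq[-1]
            if dmax == 0:
                w = np.ones(q)
            else:
                w = (1.0 - (dq / dmax) ** 3) ** 3
                w = np.clip(w, 0.0, None)
        tt, yy = t_train[order], y_train[order]
        sw = w.sum()
        tbar = (w * tt).sum() / sw
        ybar = (w * yy).sum() / sw
        sxx = (w * (tt - tbar) ** 2).sum()
        slope = (w * (tt - tbar) * (yy - ybar)).sum() / sxx if sxx > 0 else 0.0
        out[m] = ybar + slope * (x0 - tbar)
    return out


def loess_fit(t, y, span: float, degree: int = 1) -> np.ndarray:
    """LOESS fitted values at the observation points."""
    if degree != 1:
        raise ValueError("only degree 1 is supported")
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    return _loess_eval(t, y, t, span)


def select_span_cv(t, y, config: LoessConfig | None = None) -> tuple[float, dict[float, float]]:
    """Choose the LOESS span by k-fold CV on held-out squared error.

    Folds are assigned by a seeded shuffle. Spans whose neighbourhood would
    be infeasible on some training split get infinite MSE; the argmin span
    is returned, ties resolved toward the largest (smoothest) span.
    """
    config = config or LoessConfig()
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 10:
        raise ValueError("span selection requires n >= 10")
    if len(config.spans) == 1:
        return config.spans[0], {config.spans[0]: np.nan}
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, config.cv_folds)
    mse: dict[float, float] = {}
    for span in config.spans:
        errs = []
        feasible = True
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            try:
                pred = _loess_eval(t[mask], y[mask], t[fold], span)
            except ValueError:
                feasible = False
                break
            errs.append((y[fold] - pred) ** 2)
        mse[span] = float(np.mean(np.concatenate(errs))) if feasible else np.inf
    if all(np.isinf(v) for v in mse.values()):
        raise ValueError("no feasible span in the grid")
    best_mse = min(mse.values())
    best = max(s for s, v in mse.items() if v == best_mse)
    return best, mse


def detrend_yield(y, config: LoessConfig | None = None) -> tuple[np.ndarray, dict]:
    """Yield anomalies: y minus the CV-selected LOESS smooth (t/ha)."""
    y = np.asarray(y, float)
    t = np.arange(len(y), dtype=float)
    if np.std(y) == 0:
        return np.zeros_like(y), {"span": None, "note": "constant series"}
    span, mse = select_span_cv(t, y, config)
    smooth = loess_fit(t, y, span)
    return y - smooth, {"span": span, "cv_mse": mse}


def conditional_detrend_index(
    x, alpha: float = 0.05, config: LoessConfig | None = None
) -> tuple[np.ndarray, dict]:
    """Detrend an index series only when it exhibits a trend or break.

    LOESS detrending is applied when the Mann–Kendall test or the
    single-break sup-F test is significant at ``alpha``; otherwise the mean
    is subtracted. The branch decision and test results are returned as
    metadata.
    """
    x = np.asarray(x, float)
    if len(x) < 10:
        raise ValueError("conditional detrending requires n >= 10")
    mk = mann_kendall(x, alpha=alpha)
    bp = detect_breakpoint(x, alpha=alpha)
    meta: dict = {
        "mk_p": mk.p_two_sided, "bp_p": bp.p_value,
        "mk_significant": mk.significant, "bp_significant": bp.significant,
    }
    if mk.significant or bp.significant:
        t = np.arange(len(x), dtype=float)
        span, _ = select_span_cv(t, x, config)
        anomalies = x - loess_fit(t, x, span)
        meta.update(branch="loess", span=span)
    else:
        anomalies = x - x.mean()
        meta.update(branch="mean", span=None)
    return anomalies, meta


def standardize(x) -> np.ndarray:
    """Z-scores with the sample (n-1) standard deviation."""
    x = np.asarray(x, float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return (x - x.mean()) / sd


def collinearity_diagnostics(X: pd.DataFrame) -> dict:
    """VIF, tolerance and condition indices of a predictor matrix.

    VIF_j = 1/(1 - R2_j) from regressing predictor j on the others
    (with intercept); tolerance_j = 1/VIF_j. Condition indices are
    sqrt(lambda_max / lambda_i) of X'X after scaling each column (intercept
    included) to unit norm. Flags: VIF > 5, tolerance < 0.2, condition
    index > 10. Perfect collinearity yields infinite VIF with a flag.
    """
    X = pd.DataFrame(X)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    vif, tol = {}, {}
    for col in X.columns:
        others = X.drop(columns=[col])
        Z = sm.add_constant(others.to_numpy(float))
        fit = sm.OLS(X[col].to_numpy(float), Z).fit()
        r2 = min(fit.rsquared, 1.0)
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        vif[col] = float(v)
        tol[col] = float(0.0 if np.isinf(v) else 1.0 / v)
    M = np.column_stack([np.ones(n), X.to_numpy(float)])
    M = M / np.linalg.norm(M, axis=0)
    eigvals = np.linalg.eigvalsh(M.T @ M)
    eigvals = np.clip(eigvals, 0.0, None)
    lam_max = eigvals.max()
    with np.errstate(divide="ignore"):
        cond = np.sqrt(np.where(eigvals > 0, lam_max / eigvals, np.inf))
    cond = np.sort(cond)[::-1]
    return {
        "vif": vif,
        "tolerance": tol,
        "condition_indices": cond,
        "flags": {
            "vif": {c: v > 5 for c, v in vif.items()},
            "tolerance": {c: v < 0.2 for c, v in tol.items()},
            "condition_index": bool(cond.max() > 10),
        },
    }


@dataclass
class CsimFit:
    """Fitted combined-stress regression with diagnostics."""

    alpha: float
    beta: float
    gamma: float
    intercept: float
    p_values: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    r_squared: float
    csim_series: np.ndarray  # fitted values per season
    residuals: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def fit_csim(hmd_std, spei_detrended, epm_std, yield_anomalies) -> CsimFit:
    """OLS of yield anomalies on standardized HMD, SPEI and standardized EPM.

    Collinearity diagnostics are computed first and attached; the fit
    proceeds regardless of flags (screen-then-fit). Exact rank deficiency
    of the three predictors raises.
    """
    X = pd.DataFrame(
        {
            "hmd_std": np.asarray(hmd_std, float),
            "spei": np.asarray(spei_detrended, float),
            "epm_std": np.asarray(epm_std, float),
        }
    )
    y = np.asarray(yield_anomalies, float)
    if not (len(X) == len(y)):
        raise ValueError("predictor and yield lengths differ")
    if len(y) < 8:
        raise ValueError("need at least 8 seasons")
    diag = collinearity_diagnostics(X)
    Z = sm.add_constant(X.to_numpy(float))
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError("singular design: predictors are collinear")
    fit = sm.OLS(y, Z).fit()
    names = ["intercept", "hmd_std", "spei", "epm_std"]
    ci = fit.conf_int(alpha=0.05)
    return CsimFit(
        alpha=float(fit.params[1]),
        beta=float(fit.params[2]),
        gamma=float(fit.params[3]),
        intercept=float(fit.params[0]),
        p_values={nm: float(p) for nm, p in zip(names, fit.pvalues)},
        conf_int={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)},
        r_squared=float(fit.rsquared),
        csim_series=np.asarray(fit.fittedvalues, float),
        residuals=np.asarray(fit.resid, float),
        diagnostics=diag,
    )
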