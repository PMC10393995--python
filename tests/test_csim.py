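"""LOESS detrending, span CV, collinearity screen, combined-stress fit."""

import numpy as np
import pandas as pd
import pytest

from climstress.csim import (
    LoessConfig,
    collinearity_diagnostics,
    conditional_detrend_index,
    detrend_yield,
    fit_csim,
    loess_fit,
    select_span_cv,
    standardize,
)
from climstress.trend import mann_kendall


class TestLoess:
    def test_reproduces_exact_line(self):
        t = np.arange(20.0)
        y = 1.5 * t - 4.0
        for span in (0.3, 0.5, 1.0):
            np.testing.assert_allclose(loess_fit(t, y, span), y, atol=1e-9)

    def test_span_one_equals_global_ols(self):
        rng = np.random.default_rng(10)
        t = np.arange(30.0)
        y = rng.normal(size=30) + 0.2 * t
        X = np.column_stack([np.ones(30), t])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(loess_fit(t, y, 1.0), X @ beta, atol=1e-9)

    def test_constant_series_gives_constant_fit(self):
        t = np.arange(15.0)
        np.testing.assert_allclose(loess_fit(t, np.full(15, 3.3), 0.5), 3.3)

    def test_too_small_span_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            loess_fit(np.arange(30.0), np.arange(30.0), 0.05)


class TestSpanSelection:
    def test_white_noise_prefers_large_spans(self):
        # structureless data should drive the CV toward the smoothest fits:
        # simulation places ~75% of selections in the top third of the grid
        # and makes the maximum span the modal choice
        rng = np.random.default_rng(20)
        cfg = LoessConfig(seed=99)
        chosen = np.array(
            [select_span_cv(np.arange(30.0), rng.normal(size=30), cfg)[0]
             for _ in range(100)]
        )
        assert (chosen >= 0.75).mean() >= 0.6
        assert (chosen == max(cfg.spans)).mean() >= 0.4

    def test_cv_consistency_on_smooth_signal(self):
        rng = np.random.default_rng(21)
        t = np.arange(40.0)
        y = np.sin(t / 6.0) * 3.0 + rng.normal(0, 0.2, 40)
        cfg = LoessConfig(seed=5)
        span, mse = select_span_cv(t, y, cfg)
        assert mse[span] <= mse[cfg.spans[0]]
        assert mse[span] <= mse[cfg.spans[-1]]

    def test_single_candidate_returned_unchanged(self):
        cfg = LoessConfig(spans=(0.7,))
        span, _ = select_span_cv(np.arange(12.0), np.random.default_rng(0).normal(size=12), cfg)
        assert span == 0.7

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(22)
        y = rng.normal(size=25)
        cfg = LoessConfig(seed=7)
        a = select_span_cv(np.arange(25.0), y, cfg)
        b = select_span_cv(np.arange(25.0), y, cfg)
        assert a == b


class TestDetrendYield:
    def test_residuals_centred(self):
        rng = np.random.default_rng(30)
        y = rng.normal(5.0, 0.5, 30)
        anom, _ = detrend_yield(y)
        assert abs(anom.mean()) < 0.15

    def test_recovers_known_anomalies_under_logistic_trend(self):
        # deterministic short-period anomalies the smoother cannot absorb,
        # riding on a logistic technology trend, with no stochastic noise
        n = 30
        s = np.arange(n, dtype=float)
        trend = 3.0 + 2.0 / (1.0 + np.exp(-(s - 15) / 4.0))
        truth = 0.35 * np.sin(2 * np.pi * s / 4.0 + 0.3)
        anom, _ = detrend_yield(trend + truth)
        assert np.corrcoef(anom, truth)[0, 1] > 0.95

    def test_constant_yield_gives_zero_anomalies(self):
        anom, meta = detrend_yield(np.full(30, 2.5))
        np.testing.assert_array_equal(anom, 0.0)

    def test_idempotent_when_span_forced(self):
        rng = np.random.default_rng(32)
        y = rng.normal(size=30) + 0.1 * np.arange(30)
        t = np.arange(30.0)
        span = 0.6
        anom = y - loess_fit(t, y, span)
        again = anom - loess_fit(t, anom, span)
        # detrending an already-detrended series is a near-no-op
        assert np.sqrt(np.mean((again - anom) ** 2)) < np.std(y) * 0.2


class TestConditionalDetrend:
    def test_iid_noise_takes_mean_removal_branch(self):
        rng = np.random.default_rng(40)
        x = rng.normal(size=30)
        anom, meta = conditional_detrend_index(x)
        assert meta["branch"] == "mean"
        assert anom.mean() == pytest.approx(0.0, abs=1e-12)

    def test_strong_trend_takes_loess_branch_and_whitens(self):
        rng = np.random.default_rng(41)
        taken, whitened = 0, 0
        n_sim = 50
        for _ in range(n_sim):
            x = rng.normal(size=30) + 0.2 * np.arange(30)
            anom, meta = conditional_detrend_index(x)
            if meta["branch"] == "loess":
                taken += 1
                if not mann_kendall(anom).significant:
                    whitened += 1
        assert taken >= 45
        assert whitened >= 0.9 * taken

    def test_same_input_same_branch(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=30)
        a = conditional_detrend_index(x)
        b = conditional_detrend_index(x)
        assert a[1]["branch"] == b[1]["branch"]
        np.testing.assert_array_equal(a[0], b[0])


class TestStandardize:
    def test_unit_moments(self):
        rng = np.random.default_rng(50)
        z = standardize(rng.normal(3, 7, 100))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_three_point_example(self):
        np.testing.assert_allclose(standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_affine_invariance_up_to_sign(self):
        rng = np.random.default_rng(51)
        x = rng.normal(size=40)
        np.testing.assert_allclose(standardize(-2.0 * x + 5.0), -standardize(x), atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(np.full(10, 1.0))


class TestCollinearity:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({
            "a": np.where(t % 2 == 0, 1.0, -1.0),
            "b": np.where((t // 2) % 2 == 0, 1.0, -1.0),
            "c": np.where((t // 4) % 2 == 0, 1.0, -1.0),
        })
        d = collinearity_diagnostics(X)
        for col in X.columns:
            assert d["vif"][col] == pytest.approx(1.0, abs=1e-9)
            assert d["tolerance"][col] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_flagged_no_crash(self):
        rng = np.random.default_rng(60)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        d = collinearity_diagnostics(X)
        assert np.isinf(d["vif"]["a"]) and d["flags"]["vif"]["a"]

    def test_equicorrelated_design_matches_closed_form(self):
        # VIF for 3 equicorrelated predictors: R2_j = 2 rho^2 / (1 + rho)
        rho, n = 0.8, 1000
        rng = np.random.default_rng(61)
        cov = np.full((3, 3), rho)
        np.fill_diagonal(cov, 1.0)
        X = pd.DataFrame(rng.multivariate_normal(np.zeros(3), cov, size=n),
                         columns=list("abc"))
        d = collinearity_diagnostics(X)
        expected = 1.0 / (1.0 - 2 * rho**2 / (1 + rho))
        for col in "abc":
            assert d["vif"][col] == pytest.approx(expected, rel=0.10)

    def test_vif_is_reciprocal_tolerance(self):
        rng = np.random.default_rng(62)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        d = collinearity_diagnostics(X)
        for col in "abc":
            assert d["vif"][col] == pytest.approx(1.0 / d["tolerance"][col])


class TestFitCsim:
    def _design(self, n=30, seed=70):
        rng = np.random.default_rng(seed)
        hmd = standardize(rng.gamma(2.0, 2.0, n))
        spei = rng.normal(size=n)
        epm = standardize(rng.gamma(3.0, 50.0, n))
        return hmd, spei, epm

    def test_exact_linear_recovery(self):
        hmd, spei, epm = self._design()
        y = 0.5 * spei
        fit = fit_csim(hmd, spei, epm, y)
        assert fit.beta == pytest.approx(0.5, abs=1e-10)
        assert fit.alpha == pytest.approx(0.0, abs=1e-10)
        assert fit.gamma == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_orthogonal_response_gives_near_zero_r2(self):
        hmd, spei, epm = self._design(n=200, seed=71)
        rng = np.random.default_rng(72)
        y = rng.normal(size=200)
        fit = fit_csim(hmd, spei, epm, y)
        assert fit.r_squared < 0.05

    def test_r2_equals_squared_correlation_with_fitted(self):
        hmd, spei, epm = self._design(seed=73)
        rng = np.random.default_rng(74)
        y = -0.3 * hmd + 0.6 * spei + 0.3 * epm + rng.normal(0, 0.5, 30)
        fit = fit_csim(hmd, spei, epm, y)
        r = np.corrcoef(fit.csim_series, y)[0, 1]
        assert fit.r_squared == pytest.approx(r**2)

    def test_stress_season_yields_negative_csim(self):
        # hot, dry season with alpha<0, beta>0 must push CSIm down
        hmd, spei, epm = self._design(seed=75)
        rng = np.random.default_rng(76)
        y = -0.5 * hmd + 0.7 * spei + rng.normal(0, 0.1, 30)
        fit = fit_csim(hmd, spei, epm, y)
        stressed = (hmd > 1.0) & (spei < -0.5)
        if stressed.any():
            assert (fit.csim_series[stressed] < 0).all()

    def test_singular_design_raises(self):
        hmd, spei, _ = self._design()
        with pytest.raises(np.linalg.LinAlgError):
            fit_csim(hmd, spei, hmd, np.arange(30.0))

    def test_length_mismatch_rejected(self):
        hmd, spei, epm = self._design()
        with pytest.raises(ValueError):
            fit_csim(hmd, spei, epm, np.arange(29.0))

    def test_yield_detrending_mildly_attenuates_coefficients(self):
        # removing the CV-chosen LOESS smooth from yield absorbs part of
        # the predictor-aligned signal: estimates shrink toward zero by
        # roughly the smoother's df/n (~10% at n=30), never grow
        hmd, spei, epm = self._design(n=30, seed=77)
        truth = 0.6
        rng = np.random.default_rng(78)
        cfg = LoessConfig(seed=7)
        betas = []
        for rep in range(60):
            y = 4.0 + 0.07 * np.arange(30) + truth * spei + rng.normal(0, 0.7, 30)
            y_anom, _ = detrend_yield(y, cfg)
            betas.append(fit_csim(hmd, spei, epm, y_anom).beta)
        mean_beta = np.mean(betas)
        assert 0.75 * truth < mean_beta < truth + 0.03
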