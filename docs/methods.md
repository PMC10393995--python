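# Methods

`climstress` quantifies three kinds of growing-season climate extremes for
Southern-Hemisphere maize — heatwaves, drought, and extreme precipitation —
and estimates their combined contribution to inter-seasonal yield
variability. This note records the models, the defaults and why they were
chosen, and what the synthetic experiments do and do not demonstrate.

## Growing-season calendar

Seasons are labelled `"YYYY/YY+1"` and follow the Southern-Hemisphere maize
cycle: planting in October, maturity in March. Three windows are attached
to each season, all closed intervals:

* **heatwave (HMD) window**: Oct 1 – last day of February (leap-aware),
  the five months before harvest when heat stress matters most;
* **extreme-precipitation (EPM) window**: Oct 1 – Mar 31, six months, so
  that excess water during late maturity is captured;
* **drought (SPEI) window**: the five monthly SPEI-3 values Oct..Feb.

## Heatwave magnitude (HMD)

The per-calendar-day heat threshold T90(d) is the 90th percentile of the
pooled set of daily maximum temperatures in a centred 31-day window around
d, across all study seasons (~30 x 31 = 930 values per day). A heatwave is
a run of at least three consecutive days with T_d > T90(d). Each run day
contributes a normalised magnitude

    M_d = (T_d - T25max) / (T75max - T25max)   if T_d > T90(d), else 0,

where T25max/T75max are the 25th/75th percentiles of the per-season maxima
of daily Tmax over the study period. The seasonal HMD is the sum of M_d
over all heatwave-run days; the heatwave frequency is the number of such
days (hence always 0 or >= 3).

Numerical choices:

* the normalisation percentiles follow the heatwave-magnitude-index
  convention (per-season maxima); an "all-days" variant is available via
  `norm_mode` since the two readings differ materially;
* negative M_d (possible early/late in the season when T90 < T25max) is
  clamped to zero — magnitudes measure stress;
* percentiles use linear interpolation between order statistics; with
  ~930-value pools the estimator choice shifts T90 by a few hundredths of
  a degree, so it is fixed and documented rather than configurable;
* thresholds exist for Oct 1..Feb 28; Feb 29 is served by the Feb 28
  threshold; the 31-day window requires the daily record to extend from
  Sep 16 to Mar 16 around every season (checked, `WindowError` otherwise);
* exceedance is strict (`>`), matching the index definitions exactly.

## Extreme precipitation (EPM)

P95 is the 95th percentile of daily precipitation pooled over the Oct–Mar
windows of all study seasons — growing-season days only, wet and dry alike
(a wet-day-only variant is available via `p95_population`). The seasonal
EPM is the sum of precipitation on days strictly above P95; its frequency
counts those days. No run-length requirement applies.

## Drought (SPEI-3)

The monthly climatic water balance D = P - PET is summed over backward
3-month windows. Per calendar month, a three-parameter log-logistic
distribution is fitted to the aggregated values by unbiased
probability-weighted moments, and each value is mapped through the fitted
CDF and the standard normal quantile (exact `scipy` inverse, not the
rational approximation; error < 1e-6). Negative SPEI means drought.

* The log-logistic family only accommodates positive skew. Months whose
  aggregated balance is symmetric or negatively skewed (the PWM system
  then returns shape <= 1) are fitted on the reflected sample and the CDF
  complemented. The transform stays strictly monotone and calibrated.
* Calibration defaults to the full record; >= 10 values per calendar month
  are required, >= 20 recommended.
* Values outside the fitted support are clamped to CDF epsilon (1e-8,
  SPEI ~ +-5.6) with a warning.
* The seasonal drought value is the arithmetic mean of the five monthly
  SPEI-3 values Oct..Feb; a `february` mode (the February SPEI-3 already
  integrates Dec–Feb) is available. When a precomputed SPEI product is
  available it can be ingested directly, bypassing the fitting.
* PET here is a deliberately simple stand-in (see Synthetic data); the
  package standardises whatever water-balance series it is given.

## Trend diagnostics

Mann–Kendall with tie-corrected variance and +-1 continuity correction;
Sen's slope as the trend magnitude; OLS for the linear tendency; sample
ACF and Durbin–Levinson PACF flagged at 1.96/sqrt(n); and a single-break
sup-F (Chow-type) test in a mean-plus-trend model with 15% trimming.
A single break is the most that ~30 seasons can support.

The sup-F p-value is computed against a Monte-Carlo null (499 replicates,
fixed internal seed, cached per sample size): under the iid-normal
linear-trend null the statistic is pivotal for fixed n and trimming, so
the simulated null is exact in distribution up to Monte-Carlo error. This
replaces the published asymptotic response-surface approximation, which
adds transcription risk without improving small-sample accuracy at n = 30.

## Combined stress regression (CSIm)

Yield carries a slow technology trend; it is removed by LOESS (local
linear, tricube weights) with the span chosen by fivefold cross-validation
over a 0.3–1.0 grid (step 0.05), lowest held-out MSE, ties resolved toward
the smoothest span, folds assigned by a seeded shuffle. Each index series
is LOESS-detrended only if Mann–Kendall or the break test is significant
at 0.05; otherwise its mean is removed (decision recorded in metadata).
Heat and excess-water anomalies are standardized ((x - mean)/sd, n-1);
drought is standardized by construction. The regression

    CSIm_s = alpha * HMD_std + beta * SPEI + gamma * EPM_std + eps_s

is ordinary least squares with an intercept (harmless after detrending,
and it keeps the residual definition standard). Collinearity is screened
first — VIF (flag > 5), tolerance (flag < 0.2), and condition indices of
the unit-scaled design including the intercept column (flag > 10) — and
the fit proceeds regardless, carrying the flags, mirroring the
screen-then-fit order of the original procedure. Perfect collinearity
reports infinite VIF without crashing; an exactly singular design raises.

Two LOESS details are deliberate deviations from the textbook smoother:

* when the span covers the whole sample (span >= 1) the weights are
  uniform, so the smooth equals the global OLS line — the natural limit
  for "no local structure" and the contract the span grid's upper end is
  meant to express (strict tricube would zero-weight the farthest point
  and never reduce to OLS);
* held-out points beyond the training range are predicted by the local
  line at the nearest neighbourhood (local extrapolation), which is what
  makes edge folds usable in cross-validation.

**Attenuation.** Detrending the response with a data-driven smoother
absorbs whatever part of the stress signal the smoother can represent.
At n = 30 this shrinks coefficient estimates toward zero by roughly the
smoother's effective degrees of freedom over n (~7–11% measured), more if
a predictor itself has low-frequency structure. This is a property of the
detrend-then-regress design, not of the implementation; the
coefficient-recovery experiments therefore validate the regression on
trend-free anomalies, and a separate test pins the attenuation (shrinkage
bounded, never inflation).

## Nonlinearity screen and causal discovery

Pairwise index relations are screened with exact Gaussian-process
regression: squared-exponential kernel times a signal variance, plus a
white-noise kernel; inputs standardized; hyperparameters maximise the log
marginal likelihood over seeded restarts. The length scale is bounded
below by 0.5 on the standardized-input scale: shorter scales let the RBF
impersonate a second white kernel and absorb chance coincidences in
structureless data, making the signal/noise split unidentifiable. At equal
marginal likelihood a noise-only model is preferred (parsimony tie-break).

Causal structure among {HMD, SPEI, EPM} is recovered with PCMCI:

1. **condition selection** — for each variable, lagged candidate parents
   (lags 1..tau_max, all variables) are pruned by iterative
   conditional-independence tests with growing condition sets drawn from
   the strongest remaining candidates (selection level `pc_alpha = 0.2`,
   deliberately liberal so true parents survive to stage 2);
2. **momentary conditional independence** — every candidate link
   X_{t-tau} -> Y_t (tau = 0..tau_max) is tested conditioning on Y's
   selected parents (minus the tested link) and X's parents shifted by
   tau (conditions whose shifted lag would exceed tau_max are dropped —
   a truncation that matters only for tau_max-lag parents). Links with
   p <= alpha are retained; strength is the partial correlation.

The default conditional-independence test is partial correlation
(residualize both variables on the condition set, t-test on n - |Z| - 2
degrees of freedom): with ~30 seasons, nearest-neighbour mutual-information
tests are badly underpowered. A permutation-based k-NN CMI test is provided
as an option; its null uses a global shuffle, adequate for the weakly
autocorrelated seasonal series this package targets but not for strongly
dependent data. Contemporaneous (lag-0) links are reported undirected — no
orientation rule is applied — and `tau_max` defaults to one season.

## Synthetic data

The generator emulates a ~30-season single-region record with known ground
truth:

* **Tmax**: annual sinusoid peaking mid-January (Southern Hemisphere),
  default mean 22 degC and amplitude 7 degC, plus AR(1) noise (phi = 0.7,
  marginal sd 2.5 degC) — values typical of the summer-rainfall maize belt;
* **heat events**: per season a Poisson(2) number of events adds 5 degC
  over 1 + Poisson(3) consecutive days, so most injected events exceed the
  3-day heatwave threshold while some 1–2-day events act as negative
  controls for the run filter;
* **precipitation**: two-state Markov occurrence chain (P(wet|dry) = 0.25,
  P(wet|wet) = 0.55, stationary wet fraction 0.36) with gamma wet-day
  amounts (shape 0.8, scale 8 mm), plus Poisson(3) injected 40 mm extreme
  days per season;
* **water balance**: monthly precipitation minus a linear-in-Tmax PET
  stand-in (0.5 + 0.18 * Tmax mm/day, floored at zero, scaled by month
  length). This is monotone in temperature and produces realistic negative
  balances, but it is *not* a physical evapotranspiration model — only the
  standardization machinery downstream of the water balance is under test;
* **yield**: technology trend (linear by default, 2 t/ha over the record
  from a 3 t/ha base, logistic available) plus
  alpha * HMD_std + beta * SPEI + gamma * EPM_std plus Gaussian noise
  (default sd 0.4 t/ha), with defaults (alpha, beta, gamma) =
  (-0.3, 0.6, 0.3): heat hurts, wetness helps, moderate excess-water
  benefit — sign conventions matching the stress-index reading.

Everything is deterministic given the seed; noise-free limits reproduce
their closed forms exactly.

What passing tests on this generator do **not** show about real data: no
spatial correlation structure (each cell/region is independent), no
coupling between heat and drought in the generator itself (heat events do
not suppress rainfall), PET is statistical rather than physical, and yield
noise is homoscedastic Gaussian. Recovery results therefore demonstrate
correctness of the estimators, not field-scale attribution accuracy.

## Problem sizes

The test-suite experiments run at the scale the record dictates (30
seasons) with replicate counts chosen to keep Monte-Carlo error well below
the asserted margins: 10,000 replicates for test-size calibration of
Mann–Kendall, 500 for coefficient recovery and CI coverage, 200 for causal
link recovery and false-positive control, 200 for detrending branch logic,
50 randomized fixtures for exact index-oracle equivalence.

## Known limitations

* Single-break detection only; multi-break records will surface as one
  dominant break.
* The PCMCI implementation covers the standard lagged-links algorithm with
  partial-correlation or permutation-CMI tests; latent confounders and
  contemporaneous orientation are out of scope.
* LOESS degree is fixed at 1 (local linear); with ~30 points local
  quadratic neighbourhoods would be data-starved.
* Regional aggregation supports cosine-latitude weighting of cells
  (climate-first or index-first); no reprojection or polygon geometry.
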