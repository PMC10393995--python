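"""End-to-end orchestration: synthetic or user data through every stage.

A run executes ingest -> thresholds/indices -> SPEI -> trend -> combined
stress regression -> causal discovery, writing every stage output plus a
manifest (config, seed, version, file list). One global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence.spawn``, so each stage
is individually reproducible and a rerun with the same config and seed is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .causality import gpr_fit, pcmci
from .csim import (
    LoessConfig,
    conditional_detrend_index,
    detrend_yield,
    fit_csim,
    standardize,
)
from .data_io import SeasonWindow, read_daily_csv, read_yield_csv, season_labels
from .indices import build_threshold_climatology, season_index_table
from .spei import aggregate_k_months, fit_spei_params, seasonal_spei, spei_transform
from .synthetic import (
    WeatherGenParams,
    YieldGenParams,
    generate_daily_weather,
    generate_water_balance,
    generate_yield,
    write_yield_csv,
)
from .trend import autocorr_screen, linear_trend, mann_kendall

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Everything one full analysis run needs.

    Either provide ``climate_csv`` + ``yield_csv`` (per-region inputs), or
    leave them None to generate a synthetic dataset from ``weather`` /
    ``yield_gen`` with the configured seed.
    """

    out_dir: str = "results/run"
    seed: int = 0
    n_seasons: int = 30
    start_year: int = 1986
    climate_csv: str | None = None
    yield_csv: str | None = None
    weather: WeatherGenParams | None = None
    yield_gen: YieldGenParams | None = None
    heat_pct: float = 90.0
    precip_pct: float = 95.0
    norm_mode: str = "season-max"
    p95_population: str = "all-days"
    spei_scale: int = 3
    spei_seasonal_mode: str = "mean"
    loess: LoessConfig = field(default_factory=LoessConfig)
    alpha: float = 0.05
    tau_max: int = 1
    ci_test: str = "parcorr"
    gpr_restarts: int = 5


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    seasons = season_labels(config.start_year, config.n_seasons)
    outputs: dict[str, str] = {}

    # --- ingest or synthesize -------------------------------------------------
    if config.climate_csv is not None:
        daily = read_daily_csv(config.climate_csv, unit_id="user")
    else:
        wp = config.weather or WeatherGenParams(
            n_seasons=config.n_seasons, start_year=config.start_year, seed=seeds[0]
        )
        daily = generate_daily_weather(wp)
        daily.to_csv(out / "climate_daily.csv")
        outputs["climate_daily"] = str(out / "climate_daily.csv")

    # --- thresholds and indices ----------------------------------------------
    clim = build_threshold_climatology(
        daily, seasons,
        heat_pct=config.heat_pct, precip_pct=config.precip_pct,
        norm_mode=config.norm_mode, p95_population=config.p95_population,
    )

    # --- SPEI ----------------------------------------------------------------
    wb = generate_water_balance(daily)
    d3 = aggregate_k_months(wb, k=config.spei_scale)
    params = fit_spei_params(d3, scale_months=config.spei_scale)
    spei_monthly = spei_transform(d3.dropna(), params)
    spei_seasonal = pd.Series(
        {lbl: seasonal_spei(spei_monthly, SeasonWindow(lbl), mode=config.spei_seasonal_mode)
         for lbl in seasons},
        name="spei_seasonal",
    )
    spei_df = pd.DataFrame(
        {"year": spei_monthly.index.year, "month": spei_monthly.index.month,
         "value": spei_monthly.to_numpy()}
    )
    spei_df.to_csv(out / "spei_monthly.csv", index=False)
    outputs["spei_monthly"] = str(out / "spei_monthly.csv")

    indices = season_index_table(daily, seasons, clim, spei_seasonal=spei_seasonal)
    indices.to_csv(out / "indices.csv")
    outputs["indices"] = str(out / "indices.csv")

    # --- yield ---------------------------------------------------------------
    if config.yield_csv is not None:
        yields = read_yield_csv(config.yield_csv)
        if not set(seasons) <= set(yields.index):
            raise FileNotFoundError("yield file does not cover the season range")
        yields = yields.loc[seasons]
    else:
        yp = config.yield_gen or YieldGenParams(seed=seeds[1])
        yp = dataclasses.replace(yp, seed=seeds[1]) if config.yield_gen is None else yp
        yields = generate_yield(indices, yp)
        write_yield_csv(yields, out / "yield.csv")
        outputs["yield"] = str(out / "yield.csv")

    # --- trend reports -------------------------------------------------------
    trend_rows = []
    for name in ("hmd", "spei_seasonal", "epm"):
        x = indices[name].to_numpy(float)
        mk = mann_kendall(x, alpha=config.alpha)
        slope, intercept, p_lin = linear_trend(x)
        ac = autocorr_screen(x, max_lag=min(10, len(x) - 3))
        trend_rows.append(
            {"index": name, "Z": mk.Z, "p": mk.p_two_sided, "sen_slope": mk.sen_slope,
             "significant": mk.significant, "ols_slope": slope, "ols_p": p_lin,
             "acf_lag1": float(ac["acf"][1]), "acf_flagged_lags": int(ac["acf_flagged"].sum())}
        )
    trend_df = pd.DataFrame(trend_rows)
    trend_df.to_csv(out / "trend.csv", index=False)
    outputs["trend"] = str(out / "trend.csv")

    # --- combined stress regression ------------------------------------------
    loess_cfg = dataclasses.replace(config.loess, seed=seeds[2])
    y_anom, y_meta = detrend_yield(yields.to_numpy(float), loess_cfg)
    hmd_anom, hmd_meta = conditional_detrend_index(
        indices["hmd"].to_numpy(float), alpha=config.alpha, config=loess_cfg)
    spei_anom, spei_meta = conditional_detrend_index(
        indices["spei_seasonal"].to_numpy(float), alpha=config.alpha, config=loess_cfg)
    epm_anom, epm_meta = conditional_detrend_index(
        indices["epm"].to_numpy(float), alpha=config.alpha, config=loess_cfg)
    fit = fit_csim(standardize(hmd_anom), spei_anom, standardize(epm_anom), y_anom)

    coeff = pd.DataFrame(
        [{"alpha": fit.alpha, "beta": fit.beta, "gamma": fit.gamma,
          "intercept": fit.intercept, "r_squared": fit.r_squared,
          "p_alpha": fit.p_values["hmd_std"], "p_beta": fit.p_values["spei"],
          "p_gamma": fit.p_values["epm_std"],
          "max_vif": max(fit.diagnostics["vif"].values()),
          "max_condition_index": float(fit.diagnostics["condition_indices"].max()),
          "yield_loess_span": y_meta["span"],
          "hmd_branch": hmd_meta["branch"], "spei_branch": spei_meta["branch"],
          "epm_branch": epm_meta["branch"]}]
    )
    coeff.to_csv(out / "csim_fit.csv", index=False)
    outputs["csim_fit"] = str(out / "csim_fit.csv")
    series = pd.DataFrame(
        {"season_label": seasons, "yield_anomaly": y_anom, "csim": fit.csim_series}
    )
    series.to_csv(out / "csim_series.csv", index=False)
    outputs["csim_series"] = str(out / "csim_series.csv")

    # --- causality ------------------------------------------------------------
    gpr_rows = []
    for xname, yname in (("hmd", "epm"), ("hmd", "spei_seasonal")):
        g = gpr_fit(indices[xname].to_numpy(float), indices[yname].to_numpy(float),
                    n_restarts=config.gpr_restarts, seed=seeds[3])
        gpr_rows.append(
            {"predictor": xname, "response": yname,
             "signal_variance": g.signal_variance, "length_scale": g.length_scale,
             "noise_variance": g.noise_variance, "lml": g.log_marginal_likelihood}
        )
    pd.DataFrame(gpr_rows).to_csv(out / "gpr.csv", index=False)
    outputs["gpr"] = str(out / "gpr.csv")

    graph = pcmci(indices[["hmd", "spei_seasonal", "epm"]], tau_max=config.tau_max,
                  alpha=config.alpha, ci_test=config.ci_test, seed=seeds[3])
    graph.to_json(out / "graph.json")
    graph.to_edgelist_csv(out / "graph_edges.csv")
    outputs["graph"] = str(out / "graph.json")
    outputs["graph_edges"] = str(out / "graph_edges.csv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_seasons": config.n_seasons,
        "start_year": config.start_year,
        "outputs": outputs,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
            if isinstance(v, (int, float, str, bool, type(None)))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = str(out / "manifest.json")
    return manifest
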