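# Example configuration for `climstress run --config analysis/run_example.toml`.
# Any RunConfig field can be set here; [weather] overrides the synthetic
# generator defaults. Omit climate_csv/yield_csv to run fully synthetic.

out_dir = "results/run_example"
seed = 42
n_seasons = 30
start_year = 1986
tau_max = 1
alpha = 0.05

[weather]
n_seasons = 30
start_year = 1986
t_mean_annual = 22.0
t_seasonal_amplitude = 7.0
heat_event_rate = 2.0
rain_event_rate = 3.0
seed = 42
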