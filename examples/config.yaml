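# Full pipeline configuration with every block spelled out.
# Run:  satkit run-all --config examples/config.yaml --seed 7 --out results/demo
seed: 7
out_dir: results/demo

design:
  n_types: 8
  items_per_type: 48
  n_lists: 4
  sentences_per_list: 96
  instances_per_type_per_list: 12
  n_tones: 15
  tone_interval: 0.350
  tone_lead: 0.200
  response_period: 5.000

generative:
  n_participants: 22
  trials_per_cell: 48          # all four lists over four sessions
  ability_slope_lambda: 0.3    # d' per ability SD, asymptote only
  lambda_sd: 0.3
  beta_log_sd: 0.25
  delta_sd: 0.2
  switch_prob: 0.0
  control_lambda_fraction: 0.8
  # true_params defaults to the community-cohort averaged 3λ-1β-2δ row;
  # override per construction like so:
  # true_params:
  #   NoInterp: {lam: 3.897, beta: 0.826, delta: 0.831}
  #   OR:       {lam: 2.690, beta: 0.826, delta: 1.223}
  #   OR+SR:    {lam: 1.489, beta: 0.826, delta: 1.223}

scoring:
  average_method: pool   # pool counts before the z-transform ('mean' also available)
  asymptote_m: 4         # empirical asymptote = mean of the last 4 d' values
  # fit_lags defaults to lags 2..15 (the 14 post-onset tones)

models: ["1λ-1β-1δ", "2λ-1β-1δ", "3λ-1β-1δ", "3λ-1β-2δ", "3λ-1β-3δ", "3λ-2β-1δ"]
comparisons:
  - ["1λ-1β-1δ", "2λ-1β-1δ"]
  - ["2λ-1β-1δ", "3λ-1β-1δ"]
  - ["3λ-1β-1δ", "3λ-1β-2δ"]
  - ["3λ-1β-2δ", "3λ-1β-3δ"]
  - ["3λ-1β-1δ", "3λ-2β-1δ"]

fit:
  restarts: 10
  algorithms: ["L-BFGS-B", "Powell", "TNC", "Nelder-Mead"]
  bounds:
    lambda: [0.0, 6.0]   # d'; raise the floor to 0.4 to reproduce boundary fits
    beta: [0.05, 6.0]    # 1/s
    delta: [0.0, 3.0]    # s
  asymptote_margin: 1.0

selection:
  avg_threshold: 0.005
  majority: 0.5
  tie_break: delta

inference:
  quantities: [empirical_asymptote, lambda, beta, delta]
  ability: true
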