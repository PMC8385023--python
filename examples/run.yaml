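# Desk-scale pipeline run on a synthetic cohort with planted signal.
synth:
  n_low: 43
  n_high: 55
  n_regions: 30
  n_networks: 8
  n_informative_edges: 10
  effect_size: 1.5
  covariate_confounding: 0.0
  cognition_r2: 0.6
  noise_sd: 0.3
  ts_length: 192
  seed: 0          # overridden by the pipeline's derived synth stage seed
label: episodes
positive_class: null
fd_threshold: 0.2
residualization: paper
bootstraps: 200
fraction: 0.9
k_per_run: 50
thresholds: null    # 15%..95% of B in 5% steps
repeats: 20
outer: 3
inner: 10
inner_keep: 0.8
fdr_level: 0.05
seed: 12
outdir: null
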