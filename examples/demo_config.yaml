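# Demo pipeline configuration: a small but complete synthetic study.
# Run with:  stratmeth run --config examples/demo_config.yaml --out demo_run
seed: 7
cohort:
  n_samples: 103        # discovery cohort; quintile strata 41/41
  n_snps: 600
  n_blocks: 30
  n_probes: 1500
  n_coupled_probes: 30
  coupling_effect: 0.6
validation_n: 67        # independent validation cohort; strata 27/27
prs:
  maf_min: 0.05
  info_min: 0.8
  clump_kb: 250
  clump_r2: 0.1
  p_threshold: 0.105    # or "optimize" for the Nagelkerke grid search
strata:
  fraction: 0.4
methqc:
  range_min: 0.05
  r_min: 0.3
  use_brain_filter: true   # set false for the supplementary-EWAS design
ewas:
  moderate_var: true
  n_sv: auto
  bacon_iters: 5000
  bacon_burnin: 2000
  alpha: 0.05
pmps:
  thresholds: [0.002, 0.01, 0.05]
enrich:
  mode: union
  fdr: 0.05
  basal_up: 5000
  basal_down: 1000
  distal: 5000
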