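{
  "faces_effect_0.5sd_n66": {
    "power": 0.96,
    "reps": 400,
    "alpha": 0.05,
    "description": "Detection rate of a planted 0.5-SD FACES effect on PMPS in the exploratory family-environment model at n=66 (simulation pilot committed with the suite; test reruns a smaller replicate and compares within binomial tolerance)."
  },
  "pmps_prs_correlation_coupling_0.4": {
    "r_threshold": 0.3,
    "description": "Minimum target-set PMPS~PRS correlation at coupling 0.4, n=200 discovery / n=200 target; fixed ahead of the acceptance run."
  }
}
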