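# Demo config for `miredit run --config examples/pipeline_config.yaml`.
# Simulates a small two-group cohort, then runs every downstream stage.
outdir: miredit-demo-run
rng_seed: 3
alpha: 0.05
simulate:
  n_hairpins: 6
  coverage_mean: 300
  group_sizes: [4, 4]
  planted_sites:
    - {mature_id: sim-mir-001-3p, position: 6, fraction_control: 0.85, fraction_case: 0.40}
  error_rate: 0.01
  rng_seed: 3
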