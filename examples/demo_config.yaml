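# Demo pipeline configuration: all three stages on synthetic data.
# Run with:  scassembly run --config examples/demo_config.yaml --out pipeline_out
seed: 1
stages:
  dissociation:
    genotypes: [WT, L102E, L106E, L102E/L106E]
    forces: [0.05]
    n_seeds: 2
    duration_ns: 100.0
  imaging:
    separations_nm: [150.0, 350.0]
    n_seeds: 3
  counts:
    n_tubules: 200
    burst_fractions:
      WT: 0.015
      L106E: 0.161
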