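# Demo pipeline configuration: a small synthetic corpus through every stage.
#   songdev run --config examples/run_config.yaml --seed 11 --outdir runs/demo
seed: 11
outdir: runs/demo
stages: [synthetic, maturity, devmodel, entropy, simulate, shifts]
synthetic:
  n_birds: 1
  syllables_per_bird: 2
  k: 4
  renditions_per_day: 400
  age_range: [60, 66]
  day_window: [7.2, 19.2]
maturity:
  architecture: pyramid
  l2_weight: 1.0e-4
  n_permutations: 100
devmodel:
  architecture: narrow64
  max_epochs: 60
  patience: 10
entropy:
  # support filter scaled to this corpus's singing rate (default 30 assumes
  # dense singing; see docs/methods.md)
  min_count: 10
shifts:
  min_n: 20
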