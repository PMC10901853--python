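# Small sensitivity ensemble: vary degassing and the basalt/granite split.
seed: 2
output_dir: runs/demo_ensemble

world:
  generator: dispersed
  n_blocks: 4
  land_fraction: 0.30

forcing:
  o2_mixing_ratio: 0.21

ensemble:
  n_members: 5
  degassing_range: [0.75, 1.25]
  lithology_shift: [-0.2, 0.2]
  rng_seed: 2
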