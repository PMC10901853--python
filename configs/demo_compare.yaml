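# Supercontinent vs dispersed continents at equal land area and forcing.
# Calibration is done on world_b (the dispersed reference), so the comparison
# isolates the effect of plant geographic range on steady-state CO2.
seed: 1
output_dir: runs/demo_compare

forcing:
  o2_mixing_ratio: 0.21
  degassing_rel: 1.0

compare:
  world_a:
    generator: supercontinent
    land_fraction: 0.30
    center_lat: 0.0
  world_b:
    generator: dispersed
    n_blocks: 4
    land_fraction: 0.30
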