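# Run a supercontinent world to carbon-cycle steady state.
# Rate constants are calibrated on this world at reference forcing, then the
# configured forcing is applied.  Any omitted key takes its documented default
# (see the resolved_config.yaml the run emits for the full set).
seed: 1
output_dir: runs/demo_simulate

world:
  generator: supercontinent
  n_lat: 40
  n_lon: 48
  land_fraction: 0.30
  center_lat: 0.0
  basalt_fraction: 0.25

forcing:
  time_Ma: 200.0        # Myr before present (dims the sun by ~2%)
  o2_mixing_ratio: 0.21
  degassing_rel: 1.1    # 10% above reference volcanic CO2 input
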