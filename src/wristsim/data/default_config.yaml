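# Default wristsim configuration.
# Axis gains were produced by the package's Ziegler-Nichols tuning
# routine on the default plant (downward orientation) with the
# documented per-strategy derating, then frozen here.
# Units: angles deg, forces N, torques N m, lengths mm.
plant: {}
muscles: default
controllers:
  position:
    axis_gains:
    - kp: 0.28446
      ki: 8.78195
      kd: 0.002303
      integral_limit: 60.0
    - kp: 0.264
      ki: 8.35565
      kd: 0.002085
      integral_limit: 60.0
  hybrid:
    axis_gains:
    - kp: 0.28446
      ki: 17.5639
      kd: 0.018428
      integral_limit: 60.0
    - kp: 0.264
      ki: 16.71129
      kd: 0.016683
      integral_limit: 60.0
    f0: 10.0
    hysteresis_band: 2.0
  cascade:
    axis_gains:
    - kp: 0.12632
      ki: 3.68432
      kd: 0.001083
      integral_limit: 60.0
    - kp: 0.14414
      ki: 4.50449
      kd: 0.001153
      integral_limit: 60.0
    rho: 140.0
    ff_gain: 1.0
  force: {}
trajectory:
  motion: FE30
  period: 4.0
  n_cycles: 3
experiment:
  strategies:
  - position
  - hybrid
  - cascade
  orientations:
  - downward
  - upward
  motions:
  - FE30
  - RUD10
  repeats: 5
  seed: 0
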