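# Default study configuration: the resting-state network and drive.
network:
  n_units: 240
  sparseness: 0.2
  conn_mean: 49.881
  conn_sd: 4.988
  gain: 0.09522664340931418   # gamma_for_G(0.95, 0.2, 49.881)
  tau: 0.020
  dt: 0.001
  seed: 0
noise:
  mean: 20.0
  sd: 11.5
  dc_offset: 0.0
  seed: 0
protocol:
  block_length: 1800.0
  discard: 600.0
  conditions:
  - [rest, 0.0]
  - [recall, 12.5]
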