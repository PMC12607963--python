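# RXSGLD: equal-temperature guiding ladder on the skewed double well.
# Run with: sgsim rx --config examples/sdw_ladder.yaml --cycles 60
system:
  kind: sdw
integrator:
  dt: 0.001
  temperature: 300.0
  seed: 1
  record_every: 100
guiding:
  mode: SGLD
  t_L: 0.2
  gamma: 10.0
stages:
  - {T: 300.0, lambda: 0.0}
  - {T: 300.0, lambda: 0.3333}
  - {T: 300.0, lambda: 0.6667}
  - {T: 300.0, lambda: 1.0}
output:
  dir: ladder_out
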