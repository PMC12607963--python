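# SGLD on the skewed double well: 1 ns at 300 K, guiding lambda = 1.
system:
  kind: sdw
  a: 1.0        # well depth, kcal/mol
  b: 0.25       # skew, kcal/mol
  c: 1000.0     # x/z restraint, kcal/mol/A^2
  y0: 1.0       # well half-separation, A
integrator:
  dt: 0.001         # ps
  n_steps: 1000000
  temperature: 300.0
  seed: 300
  record_every: 20
  traj_every: 20
guiding:
  mode: SGLD
  t_L: 0.2          # ps
  gamma: 10.0       # 1/ps
  lambda: 1.0
  mu: 0.0
output:
  dir: sdw_out
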