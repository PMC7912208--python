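# Underdamped Langevin dynamics in the quartic double well at high friction,
# projected onto x: KM-gEDMD offset scan against the exact-parameter
# reference of the overdamped twin process, and a two-state PCCA split.
model:
  potential: doublewell
  kind: underdamped
  beta: 0.4
  gamma: 10.0
simulation:
  dt: 1.0e-3
  steps: 2000000
  seed: 8
rc:
  name: x
basis:
  family: gaussian
  centers: linspace(-2.5, 2.5, 15)
  bandwidth: 0.1
estimator:
  reference: ol-twin
  offsets: [1.0e-3, 1.0e-2, 1.0e-1, 2.0e-1, 5.0e-1, 1.0]
  mass_tol: 1.0e-6
analysis:
  n_timescales: 1
  km_offset: 1.0e-3
  bins: 50
  K: 2
  grid: [-1.8, 1.8]
  grid_n: 200
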