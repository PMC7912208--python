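# Overdamped Langevin dynamics in the lemon-slice potential, projected onto
# the polar angle: exact-parameter reference, Kramers-Moyal offset scan,
# binned effective coefficients, and a four-state PCCA decomposition.
model:
  potential: lemon
  kind: overdamped
  beta: 1.0
  gamma: 1.0
simulation:
  dt: 1.0e-3
  steps: 5000000
  seed: 42
rc:
  name: polar-angle
basis:
  family: gaussian
  centers: linspace(-2.8, 2.8, 15)
  bandwidth: 0.1
estimator:
  reference: reversible
  offsets: [1.0e-3, 5.0e-3, 1.0e-2, 5.0e-2, 1.0e-1]
  mass_tol: 1.0e-10
analysis:
  n_timescales: 3
  km_offset: 1.0e-3
  bins: 50
  K: 4
  grid: [-3.1, 3.1]
  grid_n: 200
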