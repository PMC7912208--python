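# Five-atom chain molecule: overdamped dynamics in 15 dimensions projected
# onto the two backbone dihedral angles; tensor periodic-Gaussian basis,
# KM offset scan and a six-state PCCA decomposition.
model:
  potential: chain5
  kind: overdamped
  beta: 1.0
  gamma: 1.0
simulation:
  dt: 5.0e-3
  steps: 1000000
  seed: 3
rc:
  name: chain5-dihedrals
basis:
  family: periodic_gaussian
  centers: linspace(-3.14159265, 2.35619449, 8)   # 8 of 8 equal steps on the circle
  centers_y: linspace(-3.14159265, 2.35619449, 8)
  bandwidth: 0.2
estimator:
  reference: reversible
  offsets: [5.0e-3, 1.5e-2, 5.0e-2]
  mass_tol: 1.0e-8
analysis:
  n_timescales: 5
  K: 6
  grid: [-3.14159265, 3.14159265]
  grid_n: 40
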