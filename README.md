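# projgen

Spectral analysis of **projected (coarse-grained) generators** of diffusion
processes: simulate Langevin dynamics in bundled model potentials, build
data-driven Galerkin models of the generator restricted to a reaction
coordinate, and analyze the resulting slow spectra — implied timescales,
metastable decompositions, effective drift/diffusion, and eigenvalue error
diagnostics.

The package is aimed at people studying model reduction of stochastic
dynamics (molecular kinetics, metastable systems): it answers, on concrete
systems, *how well the slow eigenvalues of a full diffusion survive
projection onto a reaction coordinate*, and *how robust data-driven
estimates of those eigenvalues are when exact system parameters are replaced
by finite-difference (Kramers–Moyal) surrogates.*

## The model and the estimators

A reversible diffusion `dX_t = b(X_t) dt + σ(X_t) dB_t` with invariant
measure μ has an infinitesimal generator

    L f = b · ∇f + ½ a : ∇²f,          a = σσᵀ,

whose eigenvalues `0 = κ₀ < κ₁ ≤ κ₂ …` are relaxation rates; their
reciprocals `tᵢ = 1/κᵢ` are the implied timescales of the slow dynamics.
Given a coarse-graining map ξ (a reaction coordinate) and a dictionary of
functions `φᵢ(ξ(x))`, a Galerkin model for the projected generator is the
generalized eigenvalue problem

    ⟨−L ψ̂, φⱼ⟩_μ = ω̂ ⟨ψ̂, φⱼ⟩_μ ,

whose matrices are estimated from a long trajectory `x₁ … x_M` in one of
three ways:

* **reversible** (exact parameters): `½M⁻¹ Σ ∇φᵢᵀ a ∇φⱼ` — the Dirichlet
  form, symmetric;
* **nonreversible** (exact parameters): `−M⁻¹ Σ [b·∇φᵢ + ½ a:∇²φᵢ] φⱼ`;
* **km** (no parameters needed): the same expression with `b, a` replaced by
  first and second conditional moments of the finite difference
  `d_s ξ(x_m) = ξ(x_{m+s/Δt}) − ξ(x_m)` at a time offset `s`.

By the min–max principle the Ritz values satisfy `κᵢ ≤ ωᵢ ≤ ω̂ᵢ`, and the
relative eigenvalue error of the projection is bounded by the *energy-norm*
(Dirichlet-form) projection error of the eigenfunction — a bound this
package verifies numerically on an Ornstein–Uhlenbeck bench with
deliberately oscillating reaction coordinates `ξ_m(x,y) = x + 0.1 sin(my)`.

Bundled systems: a 2D harmonic (OU) potential, the four-minimum "lemon
slice" potential (polar-angle coordinate), a tilted quartic double well
(overdamped and underdamped/inertial dynamics), and a five-atom chain
molecule in 15 dimensions with two dihedral coordinates and six metastable
states.

## Worked example

Overdamped dynamics in the lemon-slice potential, projected onto the polar
angle, with a 15-function Gaussian dictionary:

```python
import numpy as np
from projgen import (make_model, lemon_slice_potential, simulate_em,
                     polar_angle, gaussian_basis, GeneratorEDMD, offset_scan)

model = make_model("overdamped", lemon_slice_potential(), beta=1.0, gamma=1.0)
traj = simulate_em(model, dt=1e-3, n_steps=1_000_000, seed=42)

basis = gaussian_basis(np.linspace(-2.8, 2.8, 15), bandwidth=0.1)
ref = GeneratorEDMD(basis=basis, rc=polar_angle(), estimator="reversible",
                    model=model).fit(traj)
print(np.round(ref.timescales_[:3], 3))

scan = offset_scan(traj, polar_angle(), basis,
                   offsets=[1e-3, 1e-2, 0.1], reference=ref.spectral_,
                   n_timescales=3)
print(scan[["offset", "E_1", "E_2", "E_3"]].round(3))
```

Output:

```
[2.632 0.964 0.751]
   offset    E_1    E_2    E_3
0   0.001  0.009  0.005  0.003
1   0.010  0.083  0.065  0.065
2   0.100  0.173  0.152  0.149
```

The three numbers are the dominant implied timescales of the angular
dynamics — the mean waiting times of the transitions between the four
potential minima (slowest: the two bottom-to-top routes around the barrier).
The scan shows the central robustness result: replacing exact drift and
diffusion by Kramers–Moyal differences changes the slow eigenvalues by less
than ~20% even when the offset `s` grows by two orders of magnitude, as long
as `s` stays well below the slow timescales themselves.

The same pipeline is scriptable from the shell:

```sh
projgen simulate --model lemon --beta 1 --gamma 1 --dt 1e-3 \
        --steps 1000000 --seed 42 --out lemon.npz
projgen run --config src/projgen/configs/lemonslice.yaml --out results/
projgen bound --m-list 0..10 --out bound.csv
```

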