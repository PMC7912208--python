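# Methods

This note records the models, estimators, numerical choices, and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Dynamics and simulation

Two dynamical models are implemented on every bundled potential `V`:

* **Overdamped Langevin**: `dX = −γ⁻¹∇V dt + √(2/(βγ)) dB`, uniformly
  elliptic, reversible with respect to `ρ ∝ exp(−βV)`.
* **Underdamped Langevin** on `(q, p)`: `dq = p dt`,
  `dp = (−∇V − γp) dt + √(2γ/β) dB`. The diffusion vanishes on the position
  block (hypoelliptic, flagged as not uniformly elliptic); the invariant
  density factorizes into a Boltzmann position marginal and an `N(0, 1/β)`
  momentum marginal.

Integration is explicit Euler–Maruyama with a seeded RNG inside a
numba-compiled loop; a given seed is bit-reproducible. Unless overridden,
runs start at a potential minimum and discard the first 1% of steps as
burn-in (removes the transient at negligible cost to long averages). A
divergence guard aborts with the step index when a state exceeds 10⁶ in any
component or becomes non-finite — relevant because the lemon-slice potential
has a 1/r singularity and user-supplied step sizes may be unstable.

Bundled potentials:

* `ou`: `V = (αₓx² + α_y y²)/2`, defaults `αₓ=1, α_y=5`. Exact eigenvalues
  `κ_{r,s} = (rαₓ + sα_y)/γ` with Hermite eigenfunctions — the analytic
  bench for everything else.
* `lemon`: `V(r,φ) = cos 4φ + 1/cos(φ/2) + 10(r−1)² + 1/r`. Four angular
  minima; infinite barriers at the origin and along the negative x axis, so
  the polar angle is effectively non-periodic for the dynamics (plain
  Gaussians on `[−2.8, 2.8]` are an adequate dictionary).
* `doublewell`: `V = 3x⁴ − 5x² + 1.5x + 3y²`; the x coordinate carries the
  slow barrier crossing.
* `chain5`: five "atoms" in 3D (15-dimensional state) with stiff harmonic
  bonds (k=100, r₀=1) and angles (k=20, θ₀=109.47°), a threefold cosine
  dihedral on atoms 0–3 and a twofold one on atoms 1–4 (amplitudes 2.0, i.e.
  barriers of 4 k_BT at β=1). The two dihedrals are the slow coordinates and
  define 3×2 = 6 metastable basins. The parameters are this package's own
  (chosen so that desk-scale trajectories visit all six basins many times);
  the experiment reproduces the qualitative structure — six PCCA states,
  a five-fold dominant spectrum, offset-robust timescales — not any
  published numbers.

## Galerkin estimators and eigensolve

Three estimators assemble stiffness/mass matrices over a dictionary
`φᵢ∘ξ` (see README for the formulas): the reversible Dirichlet-form
estimator, the non-reversible generator-application estimator, and the
Kramers–Moyal (KM) estimator at offset `s`. Gradients of `φᵢ∘ξ` use the
chain rule through the analytic Jacobian (and, for the non-reversible
estimator, Hessian) of the reaction coordinate. Samples at which the
coordinate or its Jacobian is singular (e.g. the lemon-slice origin) are
skipped and counted, or abort if configured. Angular outputs are wrapped
into `(−π, π]`, and KM differences of angular coordinates use minimal-image
wrapping — without it, any seam crossing contributes a spurious ~2π jump.

The generalized eigenproblem is solved by whitening: the symmetric mass
matrix is eigendecomposed and directions below `mass_tol` (relative to the
largest eigenvalue, default 1e-10) are discarded, making the numerical rank
explicit. The reversible problem is then a symmetric eigenproblem. For the
non-symmetric estimators, eigenvalues are sorted by real part; eigenpairs
with `|Im| > imag_tol·|Re|` (default 0.1) are discarded as
non-reversibility/aliasing artifacts — at large offsets the KM generator
develops complex pairs with `|Im| ~ 2π/s` that would otherwise sort below
the physical eigenvalues — and the largest imaginary part encountered is
reported. An error is raised only if fewer near-real eigenpairs remain than
requested. The eigenpair with smallest `|ω̂|` is the stationary mode;
implied timescales are the reciprocals of the remaining positive
eigenvalues, and nonpositive ones are flagged as spurious (NaN).

`mass_tol` deserves one caveat: when basis functions are centered in
regions the trajectory never visits (the outer Gaussians of the double-well
dictionary at β=0.4), their Gram directions are pure noise at the 1e-10
level and produce spurious negative or complex dominant eigenvalues in the
KM problem. The double-well configuration therefore truncates at 1e-6,
where results sit on a stable plateau (rank 13 of 15; identical results at
1e-4/rank 11).

Offset scans report `E_i^s = |ω̂ᵢˢ − ω̂ᵢ⁰| / ω̂ᵢˢ` against an
exact-parameter reference model. For underdamped data the reference is the
overdamped twin process (same potential, β, γ), since the conditioning
approach yields identically vanishing effective coefficients for
position-only coordinates of inertial dynamics. Bootstrap errors use a
moving-block bootstrap (default 100 blocks, 100 resamples) over per-block
Galerkin matrices, so KM difference pairs never straddle block boundaries.

## Basis dictionaries

Gaussians `exp(−(z−zᵢ)²/2ρ)` and periodic Gaussians
`exp(−sin²((z−zᵢ)/2)/2ρ)` with bandwidth ρ *dividing* the exponent (a
`rho_convention="multiply"` switch provides the alternative reading),
probabilists' Hermite polynomials (H₁(z)=z, H₂(z)=z²−1, …), and tensor-grid
products of one-dimensional families. Center specifications of the form
`linspace(a, b, n)` include both endpoints. All derivative evaluations are
analytic and are property-tested against finite differences.

## Kramers–Moyal effective coefficients

`km_binned` estimates the effective drift `b_ξ(z) ≈ E[d_sξ/s | ξ=z]` and
diffusion `a_ξ(z) ≈ E[(d_sξ)²/s | ξ=z]` by hard binning (default 50 uniform
bins over the observed range, or over `(−π, π]` for angles; bins with fewer
than `min_count=100` samples are masked rather than zero-filled). Hard
binning is the most direct reading of the conditional expectation; kernel
smoothing is out of scope. Grid binning is implemented for one-dimensional
coordinates, which covers every bundled experiment.

For the lemon-slice polar angle the exact coefficients follow from the
separability of the potential into `g(φ) = cos 4φ + 1/cos(φ/2)` plus radial
terms: `a_ξ = (2/(βγ)) E[r⁻²|φ]` and `b_ξ = −(g′(φ)/γ) E[r⁻²|φ]`, with the
radial factor — independent of φ — computed by Gauss–Legendre quadrature of
`∫ r^p e^{−β(10(r−1)²+1/r)} dr` on `(0.05, 4)` (the integrand vanishes to
double precision at both ends; convergence is verified by doubling the
order and demanding agreement to 1e-8). This closed form is validated
against small-offset binned KM estimates on simulated data.

## PCCA

Metastable memberships use the inner-simplex construction: K rows of the
dominant-eigenfunction matrix (constant first) are selected as simplex
vertices — first the row farthest from the centroid, then iteratively the
row with the largest residual after projecting out the directions already
chosen — and memberships are `χ = X·A⁻¹` with `A` the vertex rows. This is
deterministic and sufficient for well-separated toy spectra; the
objective-optimization refinement of more elaborate variants is out of
scope. Row sums are exactly one when the first eigenfunction is constant;
sampling noise can push entries slightly outside `[0, 1]`, so values are
clipped and renormalized with the pre-clip violation magnitude reported.
Points whose largest membership is below 0.6 are flagged as transition
states. Memberships are evaluated on a regular grid over the reduced domain
(matching how membership curves/maps are usually displayed) rather than on
data points.

## Error-bound bench

The relative-error bound for the slowest nontrivial eigenvalue,
`E₁ = (ω̂₁−κ₁)/ω̂₁ ≤ δ₁²` (the i=1 prefactor is exactly one; the explicit
i>1 prefactor is available behind `bound_prefactor`, using Ritz values as
proxies and labeled approximate), is verified on the OU process with
reaction coordinates `ξ_m = x + 0.1 sin(my)`, m = 0..10. Galerkin matrices
over ten Hermite polynomials of `ξ_m` are integrated by tensor
Gauss–Hermite quadrature against the Gaussian invariant measure; order 160
makes every reported quantity stable to better than 1e-8 under doubling
(lower orders resolve the matrices but not the m=10 eigenvalue to that
tolerance, because `sin(my)` enters polynomials of degree 18). Both
eigenfunction errors are *upper bounds* for the true projection errors —
the exact Q-orthogonal projection onto the infinite-dimensional reduced
space is not computable — which is exactly the quantity the bench is meant
to illustrate. The computed squared L² residual grows from 1.6e-3 (m=1) to
a plateau of 5.0e-3, i.e. the residual norm stays within a factor ~1.7
while the energy-norm error grows monotonically by two orders of magnitude;
the suite asserts these orderings, not absolute figures.

## Problem sizes and what passing tests show

The test suite runs reduced problem sizes chosen to keep each fixture in
the seconds range while preserving many rare-event transitions: lemon slice
10⁶ steps (the three timescales land within ~2% of their 5×10⁶-step values;
the criterion band is widened to ±20% at this size), double well 2×10⁶
steps, chain5 5×10⁵ steps at dt = 5e-3, OU fixtures 10⁵–5×10⁵ steps.
`scripts/acceptance.py` uses the full sizes (5×10⁶ / 10⁷).

The synthetic trajectories are exact realizations of the models the
estimators assume (up to Euler–Maruyama discretization bias at
dt = 10⁻³–5×10⁻³). Passing tests therefore demonstrate correctness of the
estimators and solvers under matched model assumptions; they do not probe
force-field error, thermostat artifacts, or non-Markovian memory that real
molecular data would add.

Known limitations:

* The underdamped KM route carries a genuine O(1/(γs)) inertial correction
  to the effective diffusion: at γ=10 the position-displacement variance
  over a window s=0.5 is ~20% below that of the overdamped twin, and the
  recovered slowest timescale is correspondingly ~20% high. The crossover
  behavior (useless below s=1/γ, informative above) is robust; close
  quantitative agreement with the overdamped reference requires γs ≳ 7.
* Binned KM coefficients are implemented for one-dimensional reduced
  coordinates; multi-dimensional reductions are supported everywhere else
  (gEDMD, PCCA, scans).
* No transfer-operator (finite-lag Koopman) estimators, no higher-order
  integrators, no molecular force fields or MD-format readers.
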