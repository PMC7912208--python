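"""Langevin models of the bundled toy potentials and their simulation.

The module provides

* :class:`PotentialSpec` -- an energy landscape with analytic gradient,
* :class:`SDEModel` -- overdamped / underdamped Langevin dynamics on such a
  landscape (drift, diffusion covariance, invariant log-density),
* :func:`simulate_em` -- seeded Euler-Maruyama integration (numba-compiled),
* :func:`generator_apply` / :func:`quadratic_form` -- pointwise application of
  the infinitesimal generator L f = b . grad f + 1/2 a : Hess f and the
  Dirichlet form Q(f, g) = 1/2 int a grad f . grad g dmu.

Bundled potentials: a two-dimensional harmonic ("ou") landscape
V = (ax x^2 + ay y^2)/2, the four-minimum "lemon slice" landscape in polar
form V = cos(4 phi) + 1/cos(phi/2) + 10 (r-1)^2 + 1/r, a tilted quartic
double well V = 3x^4 - 5x^2 + 1.5x + 3y^2, and a five-atom chain molecule
("chain5") with harmonic bonds/angles and two cosine dihedral terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _kernels as _k

__all__ = [
    "PotentialSpec",
    "SDEModel",
    "Trajectory",
    "SimulationDiverged",
    "ou_potential",
    "lemon_slice_potential",
    "double_well_potential",
    "chain5_potential",
    "get_potential",
    "make_model",
    "simulate_em",
    "generator_apply",
    "quadratic_form",
    "chain5_initial_state",
]


class SimulationDiverged(RuntimeError):
    """Raised when the Euler-Maruyama iteration leaves the stable region."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(
            f"simulation diverged (non-finite or |state| > {_k.DIVERGENCE_LIMIT:g}) "
            f"at step {step}"
        )


@dataclass(frozen=True)
class PotentialSpec:
    """An energy landscape with analytic gradient.

    ``energy`` and ``gradient`` accept arrays of shape (d,) or (n, d).
    The compiled scalar kernels used by the integrator are carried along in
    ``_energy_kernel`` / ``_grad_kernel`` with parameters packed in
    ``_params_array``.
    """

    name: str
    dim: int
    parameters: dict
    _energy_kernel: Callable = field(repr=False)
    _grad_kernel: Callable = field(repr=False)
    _params_array: np.ndarray = field(repr=False)

    def energy(self, x):
        x1 = np.asarray(x, dtype=float)
        single = x1.ndim == 1
        out = _k.batch_energy(self._energy_kernel, np.atleast_2d(x1), self._params_array)
        return out[0] if single else out

    def gradient(self, x):
        x1 = np.asarray(x, dtype=float)
        single = x1.ndim == 1
        x2 = np.atleast_2d(x1)
        out = _k.batch_grad(self._grad_kernel, x2, self._params_array)
        return out[0] if single else out


def ou_potential(alpha_x: float = 1.0, alpha_y: float = 5.0) -> PotentialSpec:
    """Two-dimensional harmonic potential V = (ax x^2 + ay y^2) / 2."""
    return PotentialSpec(
        name="ou",
        dim=2,
        parameters={"alpha_x": alpha_x, "alpha_y": alpha_y},
        _energy_kernel=_k.ou_energy,
        _grad_kernel=_k.ou_grad,
        _params_array=np.array([alpha_x, alpha_y], dtype=float),
    )


def lemon_slice_potential() -> PotentialSpec:
    """Four-minimum potential with infinite barriers at the origin and the
    negative x axis: V = cos(4 phi) + 1/cos(phi/2) + 10 (r-1)^2 + 1/r."""
    return PotentialSpec(
        name="lemon",
        dim=2,
        parameters={},
        _energy_kernel=_k.lemon_energy,
        _grad_kernel=_k.lemon_grad,
        _params_array=np.zeros(0, dtype=float),
    )


def double_well_potential(a4: float = 3.0, a2: float = 5.0, a1: float = 1.5,
                          cy: float = 3.0) -> PotentialSpec:
    """Tilted quartic double well V = a4 x^4 - a2 x^2 + a1 x + cy y^2."""
    return PotentialSpec(
        name="doublewell",
        dim=2,
        parameters={"a4": a4, "a2": a2, "a1": a1, "cy": cy},
        _energy_kernel=_k.doublewell_energy,
        _grad_kernel=_k.doublewell_grad,
        _params_array=np.array([a4, a2, a1, cy], dtype=float),
    )


#: Default five-atom chain parameters (energy in units of 1/beta at beta=1;
#: bond/angle force constants are stiff so the dihedrals carry the slow
#: dynamics, with barriers of 2*A1 (threefold) and 2*A2 (twofold).
CHAIN5_DEFAULTS = dict(kb=100.0, r0=1.0, ka=20.0, theta0=1.9106332362490186,
                       A1=2.0, A2=2.0)


def chain5_potential(**overrides) -> PotentialSpec:
    """Five-atom chain in 3D: harmonic bonds and angles, a threefold cosine
    dihedral on atoms 0-3 and a twofold one on atoms 1-4 (six basins)."""
    p = dict(CHAIN5_DEFAULTS)
    p.update(overrides)
    return PotentialSpec(
        name="chain5",
        dim=15,
        parameters=p,
        _energy_kernel=_k.chain5_energy,
        _grad_kernel=_k.chain5_grad,
        _params_array=np.array([p["kb"], p["r0"], p["ka"], p["theta0"],
                                p["A1"], p["A2"]], dtype=float),
    )


_POTENTIALS = {
    "ou": ou_potential,
    "lemon": lemon_slice_potential,
    "doublewell": double_well_potential,
    "chain5": chain5_potential,
}


def get_potential(name: str, **params) -> PotentialSpec:
    if name not in _POTENTIALS:
        raise ValueError(f"unknown potential {name!r}; choose from {sorted(_POTENTIALS)}")
    return _POTENTIALS[name](**params)


@dataclass(frozen=True)
class SDEModel:
    """Overdamped or underdamped Langevin dynamics on a potential.

    Overdamped:   dX = -(1/gamma) grad V dt + sqrt(2/(beta gamma)) dB,
                  a(x) = (2 / (beta gamma)) I, uniformly elliptic.
    Underdamped:  dq = p dt, dp = (-grad V - gamma p) dt + sqrt(2 gamma/beta) dB,
                  state (q, p); a vanishes on the position block, so the
                  dynamics are hypoelliptic only (``uniformly_elliptic`` False)
                  and the invariant density factorizes into a Boltzmann
                  position marginal and a Gaussian momentum marginal.
    """

    kind: str
    potential: PotentialSpec
    beta: float
    gamma: float

    @property
    def dim(self) -> int:
        return self.potential.dim if self.kind == "overdamped" else 2 * self.potential.dim

    @property
    def uniformly_elliptic(self) -> bool:
        return self.kind == "overdamped"

    @property
    def diffusion_scale(self) -> float:
        """Scalar c such that a = c I on the driven block."""
        if self.kind == "overdamped":
            return 2.0 / (self.beta * self.gamma)
        return 2.0 * self.gamma / self.beta

    def drift(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        d = self.potential.dim
        if self.kind == "overdamped":
            out = -self.potential.gradient(X) / self.gamma
        else:
            q, p = X[:, :d], X[:, d:]
            out = np.empty_like(X)
            out[:, :d] = p
            out[:, d:] = -self.potential.gradient(q) - self.gamma * p
        return out[0] if single else out

    def diffusion_cov(self, x):
        """Full covariance matrix a(x) = sigma sigma^T, shape (..., D, D)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        n = 1 if single else x.shape[0]
        D = self.dim
        a = np.zeros((n, D, D))
        c = self.diffusion_scale
        if self.kind == "overdamped":
            idx = np.arange(D)
            a[:, idx, idx] = c
        else:
            d = self.potential.dim
            idx = np.arange(d, 2 * d)
            a[:, idx, idx] = c
        return a[0] if single else a

    def invariant_log_density(self, x):
        """Unnormalized log of the invariant density."""
        x = np.asarray(x, dtype=float)
        X = np.atleast_2d(x)
        d = self.potential.dim
        if self.kind == "overdamped":
            out = -self.beta * np.atleast_1d(self.potential.energy(X))
        else:
            q, p = X[:, :d], X[:, d:]
            out = -self.beta * (np.atleast_1d(self.potential.energy(q))
                                + 0.5 * np.sum(p * p, axis=1))
        return out[0] if x.ndim == 1 else out

    def a_reduced(self, jacobian):
        """Contraction grad(xi)^T a grad(xi) for a stack of Jacobians.

        ``jacobian`` has shape (n, D, m); returns (n, m, m).  Exploits that a
        is a scalar multiple of the identity on the driven block.
        """
        J = np.asarray(jacobian)
        c = self.diffusion_scale
        if self.kind == "overdamped":
            return c * np.einsum("ndi,ndj->nij", J, J)
        d = self.potential.dim
        Jp = J[:, d:, :]
        return c * np.einsum("ndi,ndj->nij", Jp, Jp)


def make_model(kind: str, potential: PotentialSpec, beta: float, gamma: float) -> SDEModel:
    """Build an overdamped or underdamped Langevin model."""
    if kind not in ("overdamped", "underdamped"):
        raise ValueError(f"unknown kind {kind!r}; expected 'overdamped' or 'underdamped'")
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be positive")
    return SDEModel(kind=kind, potential=potential, beta=float(beta), gamma=float(gamma))


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered state table with step size and seed provenance."""

    states: np.ndarray
    dt: float
    seed: int
    burn_in_discarded: int = 0
    model_name: str = ""

    def __post_init__(self):
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "states", states)
        if states.ndim != 2 or states.shape[0] < 2:
            raise ValueError("trajectory needs at least two states (T x d table)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(states)):
            raise ValueError("trajectory contains non-finite states")

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def dim(self) -> int:
        return self.states.shape[1]


def default_initial_state(model: SDEModel) -> np.ndarray:
    """A potential minimum (momenta zero for underdamped models)."""
    name = model.potential.name
    if name == "ou":
        q = np.zeros(2)
    elif name == "lemon":
        q = np.array([np.cos(np.pi / 4), np.sin(np.pi / 4)])  # (r, phi) = (1, pi/4)
    elif name == "doublewell":
        # left minimum of 3x^4 - 5x^2 + 1.5x
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda x: model.potential.energy(np.array([x, 0.0])),
                              bounds=(-2.0, 0.0), method="bounded")
        q = np.array([res.x, 0.0])
    elif name == "chain5":
        q = chain5_initial_state(model.potential)
    else:
        q = np.zeros(model.potential.dim)
    if model.kind == "underdamped":
        return np.concatenate([q, np.zeros_like(q)])
    return q


def chain5_initial_state(potential: Optional[PotentialSpec] = None) -> np.ndarray:
    """Place the five atoms at ideal bond lengths/angles with both dihedrals
    in a basin (phi1 = pi, phi2 = 0)."""
    p = (potential or chain5_potential()).parameters
    r0, theta0 = p["r0"], p["theta0"]
    coords = np.zeros((5, 3))
    coords[1] = [r0, 0.0, 0.0]
    coords[2] = coords[1] + r0 * np.array([-np.cos(theta0), np.sin(theta0), 0.0])
    # natural-extension-reference-frame placement for atoms 3 and 4
    for i, tau in ((3, np.pi), (4, 0.0)):
        A, B, C = coords[i - 3], coords[i - 2], coords[i - 1]
        bc = C - B
        bc /= np.linalg.norm(bc)
        n = np.cross(B - A, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        local = r0 * np.array([-np.cos(theta0),
                               np.sin(theta0) * np.cos(tau),
                               np.sin(theta0) * np.sin(tau)])
        coords[i] = C + local[0] * bc + local[1] * m + local[2] * n
    return coords.reshape(-1)


def simulate_em(model: SDEModel, x0=None, dt: float = 1e-3, n_steps: int = 1000,
                seed: int = 0, burn_in: Optional[int] = None,
                noise_scale: float = 1.0) -> Trajectory:
    """Integrate the model by Euler-Maruyama with a seeded RNG.

    ``burn_in`` defaults to 1% of ``n_steps``; those initial states are
    discarded.  ``noise_scale`` multiplies the diffusion amplitude (0 gives
    the deterministic drift flow, useful for verification).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if burn_in is None:
        burn_in = n_steps // 100
    if burn_in >= n_steps:
        raise ValueError("burn_in must be smaller than n_steps")
    if x0 is None:
        x0 = default_initial_state(model)
    x0 = np.asarray(x0, dtype=float)
    pot = model.potential
    noise = noise_scale * np.sqrt(model.diffusion_scale)
    seed = int(seed) % (2 ** 31)
    if model.kind == "overdamped":
        if x0.shape != (pot.dim,):
            raise ValueError(f"x0 must have shape ({pot.dim},)")
        states, fail = _k.em_overdamped(
            pot._grad_kernel, pot._params_array, x0, dt, int(n_steps),
            int(burn_in), 1.0 / model.gamma, noise, seed)
    else:
        if x0.shape != (2 * pot.dim,):
            raise ValueError(f"x0 must have shape ({2 * pot.dim},) = (q, p)")
        states, fail = _k.em_underdamped(
            pot._grad_kernel, pot._params_array, x0[:pot.dim].copy(),
            x0[pot.dim:].copy(), dt, int(n_steps), int(burn_in),
            model.gamma, noise, seed)
    if fail >= 0:
        raise SimulationDiverged(fail)
    return Trajectory(states=states, dt=dt, seed=seed,
                      burn_in_discarded=int(burn_in),
                      model_name=f"{pot.name}:{model.kind}")


def generator_apply(model: SDEModel, f_grad, f_hess, points) -> np.ndarray:
    """Apply the generator L f = b . grad f + 1/2 a : Hess f at points.

    ``f_grad(points) -> (n, D)``; ``f_hess(points) -> (n, D, D)`` or None if
    the diffusion vanishes (not allowed otherwise).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    b = model.drift(X)
    G = np.asarray(f_grad(X))
    out = np.einsum("nd,nd->n", b, G)
    c = model.diffusion_scale
    if c != 0:
        if f_hess is None:
            raise ValueError("Hessian of f is required when the diffusion is nonzero")
        H = np.asarray(f_hess(X))
        d = model.potential.dim
        if model.kind == "overdamped":
            out = out + 0.5 * c * np.trace(H, axis1=1, axis2=2)
        else:
            out = out + 0.5 * c * np.trace(H[:, d:, d:], axis1=1, axis2=2)
    return out


def quadratic_form(model: SDEModel, f_grad, g_grad, sample_points=None,
                   quadrature=None) -> float:
    """Estimate Q(f, g) = 1/2 int a grad f . grad g dmu.

    Either ``sample_points`` (states approximately sampled from mu, Monte
    Carlo average) or ``quadrature`` = (points, normalized weights) must be
    given.  Underdamped models are rejected: the form degenerates on
    position-only observables.
    """
    if model.kind == "underdamped":
        raise ValueError("quadratic form is degenerate for underdamped models; "
                         "use an overdamped/generic model")
    if quadrature is not None:
        X, w = quadrature
        X = np.atleast_2d(np.asarray(X, dtype=float))
        w = np.asarray(w, dtype=float)
    elif sample_points is not None:
        X = np.atleast_2d(np.asarray(sample_points, dtype=float))
        w = np.full(X.shape[0], 1.0 / X.shape[0])
    else:
        raise ValueError("provide sample_points or quadrature=(points, weights)")
    Gf = np.asarray(f_grad(X))
    Gg = np.asarray(g_grad(X))
    c = model.diffusion_scale
    return float(0.5 * c * np.sum(w * np.einsum("nd,nd->n", Gf, Gg)))
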