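"""Galerkin approximation of projected generators from trajectory data.

Three estimators assemble the stiffness matrix ``<-L phi_i, phi_j>_mu`` and
the Gram (mass) matrix ``<phi_i, phi_j>_mu`` from samples ``x_m`` of the full
process, for a dictionary of functions ``phi_i`` of a reaction coordinate
``xi``:

* ``reversible``     -- the Dirichlet-form estimator
  ``1/(2M) sum grad phi_i(x_m)^T a(x_m) grad phi_j(x_m)`` (exact system
  parameters, reversible dynamics only; symmetric by construction);
* ``nonreversible``  -- ``-1/M sum [b . grad phi_i + 1/2 a : Hess phi_i] phi_j``
  (exact parameters, no reversibility assumed);
* ``km``             -- the same expression with drift and diffusion replaced
  by Kramers-Moyal finite differences of xi at a positive time offset s.

The generalized eigenproblem is solved after whitening by the mass matrix;
eigenvalue reciprocals are the implied timescales of the slow relaxation
processes.  :class:`GeneratorEDMD` wraps assembly and solution in a
scikit-learn style estimator; the module-level functions expose the
individual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .basis import BasisSet
from .coordinates import ReactionCoordinate, wrap_angle
from .models import SDEModel, Trajectory

__all__ = ["GalerkinSystem", "SpectralModel", "GeneratorEDMD",
           "assemble_reversible", "assemble_nonreversible", "assemble_km",
           "solve", "implied_timescales", "offset_scan", "bootstrap_timescales"]

_CHUNK = 200_000


@dataclass
class GalerkinSystem:
    """Stiffness-and-mass matrix pair of the generalized eigenproblem.

    ``stiffness[i, j]`` approximates ``<-L phi_i, phi_j>_mu`` (derivatives act
    on the first index); ``mass`` is the Gram matrix of the dictionary.
    """

    stiffness: np.ndarray
    mass: np.ndarray
    estimator: str
    offset: float
    n_samples: int
    n_skipped: int = 0

    def __post_init__(self):
        if not (np.all(np.isfinite(self.stiffness)) and np.all(np.isfinite(self.mass))):
            raise ValueError("Galerkin matrices contain non-finite entries")


@dataclass
class SpectralModel:
    """Sorted generator eigenvalues with coefficient vectors in the basis."""

    eigenvalues: np.ndarray          # ascending real parts, rate units
    eigenvectors: np.ndarray         # (N, k) coefficients, mass-normalized
    basis: BasisSet = field(repr=False)
    estimator: str = ""
    offset: float = 0.0
    discarded_imag: float = 0.0
    rank: int = 0

    @property
    def stationary_index(self) -> int:
        """Index of the eigenpair treated as the stationary (zero) mode."""
        return int(np.argmin(np.abs(self.eigenvalues)))

    @property
    def timescales(self) -> np.ndarray:
        """Implied timescales 1/omega_i of the non-stationary eigenvalues.

        Nonpositive eigenvalues past the stationary pair are spurious and
        reported as NaN.
        """
        idx = [i for i in range(len(self.eigenvalues)) if i != self.stationary_index]
        om = self.eigenvalues[idx]
        with np.errstate(divide="ignore"):
            t = np.where(om > 0, 1.0 / np.where(om > 0, om, 1.0), np.nan)
        return t

    def eigenfunctions(self, Z) -> np.ndarray:
        """Evaluate the approximate eigenfunctions at reduced-space points."""
        return self.basis.evaluate(Z) @ self.eigenvectors


def _finite_rows(*arrays):
    ok = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        ok &= np.isfinite(a).reshape(a.shape[0], -1).all(axis=1)
    return ok


def _iter_chunks(n, size):
    for start in range(0, n, size):
        yield slice(start, min(start + size, n))


def assemble_reversible(traj: Trajectory, rc: ReactionCoordinate, basis: BasisSet,
                        model: SDEModel, chunk_size: int = _CHUNK,
                        on_singular: str = "skip") -> GalerkinSystem:
    """Dirichlet-form estimator using exact system parameters (reversible)."""
    if not model.uniformly_elliptic:
        raise ValueError("the Dirichlet-form estimator requires a uniformly "
                         "elliptic (reversible) model; underdamped dynamics "
                         "degenerate on position-only observables")
    X = traj.states
    N = basis.n_functions
    S = np.zeros((N, N))
    G0 = np.zeros((N, N))
    used = skipped = 0
    for sl in _iter_chunks(X.shape[0], chunk_size):
        Xc = X[sl]
        Z = rc.value(Xc)
        J = rc.jacobian(Xc)
        ok = _finite_rows(Z, J)
        if not ok.all():
            if on_singular == "abort":
                raise ValueError("reaction coordinate singular at a sample point")
            skipped += int((~ok).sum())
            Xc, Z, J = Xc[ok], Z[ok], J[ok]
        Ared = model.a_reduced(J)
        G = basis.gradient(Z)
        P = basis.evaluate(Z)
        S += 0.5 * np.einsum("nia,nab,njb->ij", G, Ared, G, optimize=True)
        G0 += P.T @ P
        used += Xc.shape[0]
    return GalerkinSystem(stiffness=S / used, mass=G0 / used,
                          estimator="reversible", offset=0.0,
                          n_samples=used, n_skipped=skipped)


def _generator_on_rc(model: SDEModel, X, rc: ReactionCoordinate, J) -> np.ndarray:
    """L xi per component: b . grad xi_k + 1/2 a : Hess xi_k, shape (n, m)."""
    b = model.drift(X)
    out = np.einsum("nd,ndm->nm", b, J)
    H = rc.hessian(X)  # (n, m, d, d)
    c = model.diffusion_scale
    if model.kind == "overdamped":
        out = out + 0.5 * c * np.trace(H, axis1=2, axis2=3)
    else:
        d = model.potential.dim
        out = out + 0.5 * c * np.trace(H[:, :, d:, d:], axis1=2, axis2=3)
    return out


def assemble_nonreversible(traj: Trajectory, rc: ReactionCoordinate, basis: BasisSet,
                           model: SDEModel, chunk_size: int = _CHUNK,
                           on_singular: str = "skip") -> GalerkinSystem:
    """Generator-application estimator using exact system parameters."""
    X = traj.states
    N = basis.n_functions
    S = np.zeros((N, N))
    G0 = np.zeros((N, N))
    used = skipped = 0
    for sl in _iter_chunks(X.shape[0], chunk_size):
        Xc = X[sl]
        Z = rc.value(Xc)
        J = rc.jacobian(Xc)
        ok = _finite_rows(Z, J)
        if not ok.all():
            if on_singular == "abort":
                raise ValueError("reaction coordinate singular at a sample point")
            skipped += int((~ok).sum())
            Xc, Z, J = Xc[ok], Z[ok], J[ok]
        Lxi = _generator_on_rc(model, Xc, rc, J)
        Ared = model.a_reduced(J)
        G = basis.gradient(Z)
        H = basis.hessian(Z)
        P = basis.evaluate(Z)
        Lphi = (np.einsum("nim,nm->ni", G, Lxi)
                + 0.5 * np.einsum("nimk,nmk->ni", H, Ared, optimize=True))
        S += -(Lphi.T @ P)
        G0 += P.T @ P
        used += Xc.shape[0]
    return GalerkinSystem(stiffness=S / used, mass=G0 / used,
                          estimator="nonreversible", offset=0.0,
                          n_samples=used, n_skipped=skipped)


def _km_steps(traj: Trajectory, offset_s: float) -> int:
    k = int(round(offset_s / traj.dt))
    if k < 1 or abs(k * traj.dt - offset_s) > 1e-9 * max(1.0, abs(offset_s)):
        raise ValueError(f"offset {offset_s} is not a positive multiple of dt={traj.dt}")
    if k >= len(traj):
        raise ValueError("offset exceeds trajectory length")
    return k


def assemble_km(traj: Trajectory, rc: ReactionCoordinate, basis: BasisSet,
                offset_s: float, chunk_size: int = _CHUNK) -> GalerkinSystem:
    """Kramers-Moyal estimator at finite offset s (no system parameters).

    Angular reaction-coordinate outputs are differenced with minimal-image
    wrapping into (-pi, pi].
    """
    k = _km_steps(traj, offset_s)
    X = traj.states
    N = basis.n_functions
    S = np.zeros((N, N))
    G0 = np.zeros((N, N))
    used = skipped = 0
    Mp = X.shape[0] - k
    per = np.asarray(rc.periodic_mask, bool)
    for sl in _iter_chunks(Mp, chunk_size):
        Z0 = rc.value(X[sl])
        Z1 = rc.value(X[sl.start + k:sl.stop + k])
        ok = _finite_rows(Z0, Z1)
        if not ok.all():
            skipped += int((~ok).sum())
            Z0, Z1 = Z0[ok], Z1[ok]
        D = Z1 - Z0
        if per.any():
            D[:, per] = wrap_angle(D[:, per])
        G = basis.gradient(Z0)
        H = basis.hessian(Z0)
        P = basis.evaluate(Z0)
        DD = np.einsum("nm,nk->nmk", D, D)
        Lphi = (np.einsum("nim,nm->ni", G, D) / offset_s
                + 0.5 / offset_s * np.einsum("nimk,nmk->ni", H, DD, optimize=True))
        S += -(Lphi.T @ P)
        G0 += P.T @ P
        used += Z0.shape[0]
    return GalerkinSystem(stiffness=S / used, mass=G0 / used,
                          estimator="km", offset=float(offset_s),
                          n_samples=used, n_skipped=skipped)


def solve(system: GalerkinSystem, basis: BasisSet, n_eigs: Optional[int] = None,
          mass_tol: float = 1e-10, imag_tol: float = 0.1) -> SpectralModel:
    """Solve the generalized eigenproblem after whitening by the mass matrix.

    Directions of the dictionary whose mass eigenvalue falls below
    ``mass_tol`` times the largest are discarded (making the numerical rank
    explicit).  For the reversible estimator the reduced problem is solved as
    a symmetric one; otherwise eigenvalues are sorted by real part, the
    largest imaginary part encountered is recorded, and eigenpairs whose
    imaginary part exceeds ``imag_tol`` times their real part are dropped as
    non-reversibility/aliasing artifacts (small imaginary parts are sampling
    noise and are silently projected onto the real axis).
    """
    mass = 0.5 * (system.mass + system.mass.T)
    vals, U = np.linalg.eigh(mass)
    keep = vals > mass_tol * vals.max()
    rank = int(keep.sum())
    requested = n_eigs
    if n_eigs is None:
        n_eigs = rank
    if n_eigs > rank:
        raise ValueError(f"requested {n_eigs} eigenpairs but mass rank is {rank}")
    W = U[:, keep] / np.sqrt(vals[keep])
    discarded_imag = 0.0
    if system.estimator == "reversible":
        R = W.T @ (0.5 * (system.stiffness + system.stiffness.T)) @ W
        om, Y = np.linalg.eigh(0.5 * (R + R.T))
    else:
        # derivative acts on the first stiffness index: the eigenproblem for
        # coefficient vectors uses the transpose
        R = W.T @ system.stiffness.T @ W
        om_c, Y_c = np.linalg.eig(R)
        order = np.argsort(om_c.real)
        om_c, Y_c = om_c[order], Y_c[:, order]
        discarded_imag = float(np.max(np.abs(om_c.imag))) if om_c.size else 0.0
        scale = np.max(np.abs(om_c)) if om_c.size else 1.0
        real_enough = np.abs(om_c.imag) <= np.maximum(
            imag_tol * np.abs(om_c.real), 1e-12 * scale)
        if requested is None:
            n_eigs = int(real_enough.sum())
            if n_eigs == 0:
                raise ValueError("no near-real eigenvalues; the assembled "
                                 "generator is too far from reversible")
        elif real_enough.sum() < n_eigs:
            raise ValueError(
                f"only {int(real_enough.sum())} near-real eigenvalues "
                f"(|Im| <= {imag_tol} |Re|) available, {n_eigs} requested; "
                "the assembled generator is too far from reversible")
        om, Y = om_c.real[real_enough], Y_c.real[:, real_enough]
    om, Y = om[:n_eigs], Y[:, :n_eigs]
    norms = np.linalg.norm(Y, axis=0)
    norms[norms == 0] = 1.0
    C = W @ (Y / norms)
    return SpectralModel(eigenvalues=om, eigenvectors=C, basis=basis,
                         estimator=system.estimator, offset=system.offset,
                         discarded_imag=discarded_imag, rank=rank)


def implied_timescales(spectral: SpectralModel) -> np.ndarray:
    """Reciprocals 1/omega_i of the non-stationary eigenvalues."""
    t = spectral.timescales
    if np.any(np.isnan(t)):
        warnings.warn("nonpositive eigenvalues past the stationary pair were "
                      "flagged as spurious (NaN timescale)")
    return t


def offset_scan(traj: Trajectory, rc: ReactionCoordinate, basis: BasisSet,
                offsets: Sequence[float], reference: SpectralModel,
                n_timescales: int = 3, mass_tol: float = 1e-10,
                imag_tol: float = 0.1) -> pd.DataFrame:
    """Kramers-Moyal gEDMD across offsets, with relative errors against a
    reference spectral model.

    Returns one row per offset with the leading implied timescales ``t_i``
    and the relative eigenvalue errors ``E_i = |omega_i^s - omega_i^0| /
    omega_i^s``.  Failures of individual offsets are reported in the ``error``
    column without aborting the scan.
    """
    stat = reference.stationary_index
    om_ref = np.delete(reference.eigenvalues, stat)[:n_timescales]
    rows = []
    for s in offsets:
        row = {"offset": float(s), "error": ""}
        try:
            sm = solve(assemble_km(traj, rc, basis, s), basis,
                       mass_tol=mass_tol, imag_tol=imag_tol)
            om = np.delete(sm.eigenvalues, sm.stationary_index)[:n_timescales]
            for i, (o, o0) in enumerate(zip(om, om_ref), start=1):
                row[f"t_{i}"] = 1.0 / o if o > 0 else np.nan
                row[f"E_{i}"] = abs(o - o0) / o if o > 0 else np.inf
        except (ValueError, np.linalg.LinAlgError) as exc:
            row["error"] = str(exc)
            for i in range(1, n_timescales + 1):
                row[f"t_{i}"] = np.nan
                row[f"E_{i}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _assemble(traj, rc, basis, estimator, model=None, offset=None, **kw):
    if estimator == "reversible":
        return assemble_reversible(traj, rc, basis, model, **kw)
    if estimator == "nonreversible":
        return assemble_nonreversible(traj, rc, basis, model, **kw)
    if estimator == "km":
        if offset is None:
            raise ValueError("the Kramers-Moyal estimator requires an offset")
        return assemble_km(traj, rc, basis, offset, **kw)
    raise ValueError(f"unknown estimator {estimator!r}")


def bootstrap_timescales(traj: Trajectory, rc: ReactionCoordinate, basis: BasisSet,
                         estimator: str = "reversible", model: SDEModel = None,
                         offset: float = None, n_blocks: int = 100,
                         n_resamples: int = 100, n_timescales: int = 1,
                         seed: int = 0, mass_tol: float = 1e-10) -> np.ndarray:
    """Moving-block bootstrap of the leading implied timescales.

    The trajectory is cut into ``n_blocks`` contiguous blocks; Galerkin
    matrices are assembled per block and re-summed over block resamples, so
    Kramers-Moyal difference pairs never straddle block boundaries.  Returns
    an (n_resamples, n_timescales) array.
    """
    T = len(traj)
    edges = np.linspace(0, T, n_blocks + 1).astype(int)
    systems = []
    for b in range(n_blocks):
        sub = Trajectory(states=traj.states[edges[b]:edges[b + 1]], dt=traj.dt,
                         seed=traj.seed, model_name=traj.model_name)
        systems.append(_assemble(sub, rc, basis, estimator, model=model, offset=offset))
    weights = np.array([s.n_samples for s in systems], dtype=float)
    stiffs = np.array([s.stiffness for s in systems])
    masses = np.array([s.mass for s in systems])
    rng = np.random.default_rng(seed)
    out = np.full((n_resamples, n_timescales), np.nan)
    for r in range(n_resamples):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        w = weights[pick]
        S = np.einsum("b,bij->ij", w, stiffs[pick]) / w.sum()
        Mm = np.einsum("b,bij->ij", w, masses[pick]) / w.sum()
        sys_r = GalerkinSystem(stiffness=S, mass=Mm, estimator=systems[0].estimator,
                               offset=systems[0].offset, n_samples=int(w.sum()))
        try:
            sm = solve(sys_r, basis, mass_tol=mass_tol, imag_tol=np.inf)
            om = np.delete(sm.eigenvalues, sm.stationary_index)[:n_timescales]
            out[r, :len(om)] = np.where(om > 0, 1.0 / om, np.nan)
        except (ValueError, np.linalg.LinAlgError):
            pass
    return out


class GeneratorEDMD(BaseEstimator):
    """Data-driven Galerkin model of a projected generator.

    Parameters
    ----------
    basis : BasisSet
        Dictionary on the reduced space.
    rc : ReactionCoordinate
        Coarse-graining map from full to reduced space.
    estimator : {"reversible", "nonreversible", "km"}
        Matrix estimator; the first two need ``model`` (exact parameters),
        ``"km"`` needs ``offset``.
    model : SDEModel, optional
    offset : float, optional
        Kramers-Moyal time offset s (a multiple of the trajectory step).
    n_eigs : int, optional
        Number of eigenpairs to retain (default: mass-matrix rank).
    mass_tol, imag_tol : float
        Whitening truncation threshold and the admissible |Im|/|Re| ratio of
        dominant eigenvalues for the non-symmetric estimators.

    Attributes (after :meth:`fit`)
    ------------------------------
    system_ : GalerkinSystem
    spectral_ : SpectralModel
    eigenvalues_, eigenvectors_, timescales_ : ndarray
    discarded_imag_ : float
    rank_ : int
    """

    def __init__(self, basis=None, rc=None, estimator="reversible", model=None,
                 offset=None, n_eigs=None, mass_tol=1e-10, imag_tol=0.1,
                 chunk_size=_CHUNK):
        self.basis = basis
        self.rc = rc
        self.estimator = estimator
        self.model = model
        self.offset = offset
        self.n_eigs = n_eigs
        self.mass_tol = mass_tol
        self.imag_tol = imag_tol
        self.chunk_size = chunk_size

    def fit(self, X, y=None, dt: float = None):
        """Fit from a :class:`Trajectory` (or a T x d array plus ``dt``)."""
        if self.basis is None or self.rc is None:
            raise ValueError("basis and rc must be set before fitting")
        if not isinstance(X, Trajectory):
            if dt is None and self.estimator == "km":
                raise ValueError("pass a Trajectory or provide dt for the KM estimator")
            X = Trajectory(states=np.asarray(X, dtype=float), dt=dt or 1.0, seed=-1)
        if self.estimator in ("reversible", "nonreversible") and self.model is None:
            raise ValueError(f"estimator {self.estimator!r} requires model")
        if self.estimator == "reversible" and self.model is not None \
                and not self.model.uniformly_elliptic:
            # Dirichlet-form estimator presumes reversible elliptic dynamics
            raise ValueError("the reversible estimator requires a uniformly "
                             "elliptic (overdamped/generic) model")
        self.system_ = _assemble(X, self.rc, self.basis, self.estimator,
                                 model=self.model, offset=self.offset,
                                 chunk_size=self.chunk_size)
        self.spectral_ = solve(self.system_, self.basis, n_eigs=self.n_eigs,
                               mass_tol=self.mass_tol, imag_tol=self.imag_tol)
        self.eigenvalues_ = self.spectral_.eigenvalues
        self.eigenvectors_ = self.spectral_.eigenvectors
        self.timescales_ = self.spectral_.timescales
        self.discarded_imag_ = self.spectral_.discarded_imag
        self.rank_ = self.spectral_.rank
        return self

    def transform(self, Z):
        """Evaluate the fitted eigenfunctions at reduced-space points."""
        return self.spectral_.eigenfunctions(Z)
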