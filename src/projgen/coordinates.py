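"""Reaction coordinates: smooth maps from full state space to reduced space.

A :class:`ReactionCoordinate` bundles the map xi, its Jacobian (d x m per
point) and, where available, the Hessians of its components, together with a
per-output periodicity mask (angular outputs live in (-pi, pi]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["ReactionCoordinate", "coordinate_select", "polar_angle",
           "oscillating_rc", "dihedral", "chain5_dihedrals", "wrap_angle",
           "get_reaction_coordinate"]


def wrap_angle(x):
    """Wrap into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x), 2.0 * np.pi)


@dataclass
class ReactionCoordinate:
    name: str
    dim_full: int
    dim_reduced: int
    periodic_mask: np.ndarray
    _value: Callable = field(repr=False, default=None)
    _jacobian: Callable = field(repr=False, default=None)
    _hessian: Optional[Callable] = field(repr=False, default=None)

    def value(self, X) -> np.ndarray:
        """Evaluate xi, shape (n, m); angular outputs wrapped to (-pi, pi]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = self._value(X)
        if np.any(self.periodic_mask):
            Z = Z.copy()
            Z[:, self.periodic_mask] = wrap_angle(Z[:, self.periodic_mask])
        return Z

    def jacobian(self, X) -> np.ndarray:
        """Jacobian grad xi, shape (n, d, m)."""
        return self._jacobian(np.atleast_2d(np.asarray(X, dtype=float)))

    def hessian(self, X) -> np.ndarray:
        """Component Hessians, shape (n, m, d, d)."""
        if self._hessian is None:
            raise NotImplementedError(f"reaction coordinate {self.name!r} does not "
                                      "provide Hessians")
        return self._hessian(np.atleast_2d(np.asarray(X, dtype=float)))

    def __call__(self, X):
        return self.value(X)


def coordinate_select(indices: Sequence[int], dim_full: int,
                      name: str = None) -> ReactionCoordinate:
    """Linear projection onto a subset of state components."""
    idx = np.atleast_1d(np.asarray(indices, dtype=int))
    m = idx.size

    def value(X):
        return X[:, idx]

    def jac(X):
        J = np.zeros((X.shape[0], dim_full, m))
        J[:, idx, np.arange(m)] = 1.0
        return J

    def hess(X):
        return np.zeros((X.shape[0], m, dim_full, dim_full))

    return ReactionCoordinate(name=name or f"select{list(idx)}", dim_full=dim_full,
                              dim_reduced=m, periodic_mask=np.zeros(m, bool),
                              _value=value, _jacobian=jac, _hessian=hess)


def polar_angle(dim_full: int = 2) -> ReactionCoordinate:
    """The polar angle phi = atan2(y, x) of the first two state components.

    Singular at the origin: grad phi = (-y, x) / r^2.
    """

    def value(X):
        return np.arctan2(X[:, 1], X[:, 0])[:, None]

    def jac(X):
        x, y = X[:, 0], X[:, 1]
        r2 = x * x + y * y
        J = np.zeros((X.shape[0], dim_full, 1))
        J[:, 0, 0] = -y / r2
        J[:, 1, 0] = x / r2
        return J

    def hess(X):
        x, y = X[:, 0], X[:, 1]
        r4 = (x * x + y * y) ** 2
        H = np.zeros((X.shape[0], 1, dim_full, dim_full))
        H[:, 0, 0, 0] = 2 * x * y / r4
        H[:, 0, 1, 1] = -2 * x * y / r4
        H[:, 0, 0, 1] = H[:, 0, 1, 0] = (y * y - x * x) / r4
        return H

    return ReactionCoordinate(name="polar-angle", dim_full=dim_full, dim_reduced=1,
                              periodic_mask=np.ones(1, bool),
                              _value=value, _jacobian=jac, _hessian=hess)


def oscillating_rc(m: int, amplitude: float = 0.1) -> ReactionCoordinate:
    """xi_m(x, y) = x + amplitude * sin(m y): an oscillating perturbation of
    the plain x projection, used to probe energy-norm projection errors."""
    if m < 0 or int(m) != m:
        raise ValueError("m must be a non-negative integer")
    m = int(m)

    def value(X):
        return (X[:, 0] + amplitude * np.sin(m * X[:, 1]))[:, None]

    def jac(X):
        J = np.empty((X.shape[0], 2, 1))
        J[:, 0, 0] = 1.0
        J[:, 1, 0] = amplitude * m * np.cos(m * X[:, 1])
        return J

    def hess(X):
        H = np.zeros((X.shape[0], 1, 2, 2))
        H[:, 0, 1, 1] = -amplitude * m * m * np.sin(m * X[:, 1])
        return H

    return ReactionCoordinate(name=f"oscillating-{m}", dim_full=2, dim_reduced=1,
                              periodic_mask=np.zeros(1, bool),
                              _value=value, _jacobian=jac, _hessian=hess)


def _dihedral_values_jac(X, atoms):
    """Dihedral angle and gradient for one quadruple on flattened 3D states."""
    n = X.shape[0]
    a, b, c, d = atoms
    P = X.reshape(n, -1, 3)
    b1 = P[:, b] - P[:, a]
    b2 = P[:, c] - P[:, b]
    b3 = P[:, d] - P[:, c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    phi = np.arctan2(nb2 * np.einsum("ni,ni->n", b1, n2),
                     np.einsum("ni,ni->n", n1, n2))
    n1sq = np.einsum("ni,ni->n", n1, n1)
    n2sq = np.einsum("ni,ni->n", n2, n2)
    ga = -(nb2 / n1sq)[:, None] * n1
    gd = (nb2 / n2sq)[:, None] * n2
    s = (np.einsum("ni,ni->n", b1, b2) / nb2 ** 2)[:, None]
    t = (np.einsum("ni,ni->n", b3, b2) / nb2 ** 2)[:, None]
    gb = -(1.0 + s) * ga + t * gd
    gc = s * ga - (1.0 + t) * gd
    J = np.zeros((n, X.shape[1]))
    for atom, g in zip(atoms, (ga, gb, gc, gd)):
        J[:, 3 * atom:3 * atom + 3] = g
    return phi, J


def dihedral(atoms: Sequence[int], n_atoms: int, name: str = None) -> ReactionCoordinate:
    """Signed dihedral angle spanned by four atoms of a 3D chain
    (state = flattened coordinates).  Periodic output; no Hessian."""
    atoms = tuple(int(a) for a in atoms)
    dim_full = 3 * n_atoms

    def value(X):
        return _dihedral_values_jac(X, atoms)[0][:, None]

    def jac(X):
        return _dihedral_values_jac(X, atoms)[1][:, :, None]

    return ReactionCoordinate(name=name or f"dihedral{atoms}", dim_full=dim_full,
                              dim_reduced=1, periodic_mask=np.ones(1, bool),
                              _value=value, _jacobian=jac, _hessian=None)


def chain5_dihedrals() -> ReactionCoordinate:
    """The two backbone dihedrals (atoms 0-3 and 1-4) of the five-atom chain."""

    def value(X):
        p1, _ = _dihedral_values_jac(X, (0, 1, 2, 3))
        p2, _ = _dihedral_values_jac(X, (1, 2, 3, 4))
        return np.column_stack([p1, p2])

    def jac(X):
        _, J1 = _dihedral_values_jac(X, (0, 1, 2, 3))
        _, J2 = _dihedral_values_jac(X, (1, 2, 3, 4))
        return np.stack([J1, J2], axis=2)

    return ReactionCoordinate(name="chain5-dihedrals", dim_full=15, dim_reduced=2,
                              periodic_mask=np.ones(2, bool),
                              _value=value, _jacobian=jac, _hessian=None)


def get_reaction_coordinate(name: str, dim_full: int = 2, **kwargs) -> ReactionCoordinate:
    """Look up a bundled reaction coordinate by name."""
    if name == "x":
        return coordinate_select([0], dim_full, name="x")
    if name == "polar-angle":
        return polar_angle(dim_full)
    if name == "chain5-dihedrals":
        return chain5_dihedrals()
    if name.startswith("oscillating-"):
        return oscillating_rc(int(name.split("-", 1)[1]), **kwargs)
    raise ValueError(f"unknown reaction coordinate {name!r}")
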