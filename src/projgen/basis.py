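"""Dictionaries of reduced-space basis functions with analytic derivatives.

All families expose ``evaluate(Z) -> (n, N)``, ``gradient(Z) -> (n, N, m)``
and ``hessian(Z) -> (n, N, m, m)`` where m is the reduced dimension.  The
Gaussian families use the bandwidth convention

    phi_i(z)   = exp(-(z - z_i)^2 / (2 rho)),
    phi_i^p(z) = exp(-sin^2((z - z_i)/2) / (2 rho)),

i.e. rho is a squared width dividing the exponent (``rho_convention="divide"``,
the default); ``"multiply"`` gives exp(-rho (z - z_i)^2 / 2) instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermeval, hermeder

__all__ = ["BasisSet", "gaussian_basis", "periodic_gaussian_basis",
           "hermite_basis", "tensor_grid_basis", "linspace_centers"]


@dataclass
class BasisSet:
    """An evaluable family of reduced-space functions."""

    family: str
    dim_reduced: int
    n_functions: int
    centers: np.ndarray = None
    bandwidth: float = None
    period: float = None
    _impl: object = field(default=None, repr=False)

    def evaluate(self, Z):
        return self._impl.evaluate(_as2d(Z, self.dim_reduced))

    def gradient(self, Z):
        return self._impl.gradient(_as2d(Z, self.dim_reduced))

    def hessian(self, Z):
        return self._impl.hessian(_as2d(Z, self.dim_reduced))

    def __len__(self):
        return self.n_functions


def _as2d(Z, m):
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None] if m == 1 else Z[None, :]
    if Z.shape[1] != m:
        raise ValueError(f"expected points of dimension {m}, got {Z.shape[1]}")
    return Z


class _Gaussian1D:
    def __init__(self, centers, rho, convention):
        self.c = centers
        # effective exponent factor: value = exp(-fac * (z - c)^2)
        self.fac = 1.0 / (2.0 * rho) if convention == "divide" else rho / 2.0

    def evaluate(self, Z):
        dz = Z - self.c[None, :]
        return np.exp(-self.fac * dz ** 2)

    def gradient(self, Z):
        dz = Z - self.c[None, :]
        v = np.exp(-self.fac * dz ** 2)
        return (-2.0 * self.fac * dz * v)[:, :, None]

    def hessian(self, Z):
        dz = Z - self.c[None, :]
        v = np.exp(-self.fac * dz ** 2)
        h = (-2.0 * self.fac + 4.0 * self.fac ** 2 * dz ** 2) * v
        return h[:, :, None, None]


class _PeriodicGaussian1D:
    """phi(z) = exp(-sin^2((z - c)/2) / (2 rho)), 2 pi periodic."""

    def __init__(self, centers, rho, convention):
        self.c = centers
        self.fac = 1.0 / (2.0 * rho) if convention == "divide" else rho / 2.0

    def _parts(self, Z):
        u = 0.5 * (Z - self.c[None, :])
        s, co = np.sin(u), np.cos(u)
        v = np.exp(-self.fac * s ** 2)
        return s, co, v

    def evaluate(self, Z):
        return self._parts(Z)[2]

    def gradient(self, Z):
        s, co, v = self._parts(Z)
        return (-self.fac * s * co * v)[:, :, None]

    def hessian(self, Z):
        s, co, v = self._parts(Z)
        # d/dz (-fac s c) = -fac/2 (c^2 - s^2); plus product with gradient term
        h = (-0.5 * self.fac * (co ** 2 - s ** 2) + self.fac ** 2 * s ** 2 * co ** 2) * v
        return h[:, :, None, None]


class _Hermite1D:
    """Probabilists' Hermite polynomials H_0 .. H_{N-1}.

    H_r / sqrt(r!) are orthonormal under the standard normal weight; the
    polynomials themselves are returned (H_1(z) = z, H_2(z) = z^2 - 1, ...).
    """

    def __init__(self, n_max):
        self.n = n_max

    def _coeffs(self, r):
        c = np.zeros(r + 1)
        c[r] = 1.0
        return c

    def evaluate(self, Z):
        z = Z[:, 0]
        return np.column_stack([hermeval(z, self._coeffs(r)) for r in range(self.n)])

    def gradient(self, Z):
        z = Z[:, 0]
        out = np.column_stack([hermeval(z, hermeder(self._coeffs(r)))
                               if r > 0 else np.zeros_like(z) for r in range(self.n)])
        return out[:, :, None]

    def hessian(self, Z):
        z = Z[:, 0]
        out = np.column_stack([hermeval(z, hermeder(self._coeffs(r), 2))
                               if r > 1 else np.zeros_like(z) for r in range(self.n)])
        return out[:, :, None, None]


class _TensorProduct2D:
    def __init__(self, bx: BasisSet, by: BasisSet):
        self.bx, self.by = bx, by

    def evaluate(self, Z):
        vx = self.bx.evaluate(Z[:, :1])
        vy = self.by.evaluate(Z[:, 1:])
        return np.einsum("ni,nj->nij", vx, vy).reshape(Z.shape[0], -1)

    def gradient(self, Z):
        vx = self.bx.evaluate(Z[:, :1])
        vy = self.by.evaluate(Z[:, 1:])
        gx = self.bx.gradient(Z[:, :1])[:, :, 0]
        gy = self.by.gradient(Z[:, 1:])[:, :, 0]
        n = Z.shape[0]
        out = np.empty((n, len(self.bx), len(self.by), 2))
        out[..., 0] = np.einsum("ni,nj->nij", gx, vy)
        out[..., 1] = np.einsum("ni,nj->nij", vx, gy)
        return out.reshape(n, -1, 2)

    def hessian(self, Z):
        vx = self.bx.evaluate(Z[:, :1])
        vy = self.by.evaluate(Z[:, 1:])
        gx = self.bx.gradient(Z[:, :1])[:, :, 0]
        gy = self.by.gradient(Z[:, 1:])[:, :, 0]
        hx = self.bx.hessian(Z[:, :1])[:, :, 0, 0]
        hy = self.by.hessian(Z[:, 1:])[:, :, 0, 0]
        n = Z.shape[0]
        out = np.empty((n, len(self.bx), len(self.by), 2, 2))
        out[..., 0, 0] = np.einsum("ni,nj->nij", hx, vy)
        out[..., 1, 1] = np.einsum("ni,nj->nij", vx, hy)
        cross = np.einsum("ni,nj->nij", gx, gy)
        out[..., 0, 1] = cross
        out[..., 1, 0] = cross
        return out.reshape(n, -1, 2, 2)


def linspace_centers(start: float, stop: float, n: int) -> np.ndarray:
    """Equally spaced centers including both endpoints."""
    return np.linspace(start, stop, n)


def gaussian_basis(centers: Sequence[float], bandwidth: float,
                   rho_convention: str = "divide") -> BasisSet:
    """Gaussian bumps exp(-(z - z_i)^2 / (2 rho)) at the given centers."""
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return BasisSet(family="gaussian", dim_reduced=1, n_functions=centers.size,
                    centers=centers, bandwidth=bandwidth,
                    _impl=_Gaussian1D(centers, bandwidth, rho_convention))


def periodic_gaussian_basis(centers: Sequence[float], bandwidth: float,
                            rho_convention: str = "divide") -> BasisSet:
    """2 pi periodic bumps exp(-sin^2((z - z_i)/2) / (2 rho))."""
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return BasisSet(family="periodic_gaussian", dim_reduced=1,
                    n_functions=centers.size, centers=centers,
                    bandwidth=bandwidth, period=2 * np.pi,
                    _impl=_PeriodicGaussian1D(centers, bandwidth, rho_convention))


def hermite_basis(n_max: int) -> BasisSet:
    """The first ``n_max`` probabilists' Hermite polynomials H_0, ..,
    H_{n_max - 1}."""
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    return BasisSet(family="hermite", dim_reduced=1, n_functions=n_max,
                    _impl=_Hermite1D(n_max))


def tensor_grid_basis(basis_x: BasisSet, basis_y: BasisSet) -> BasisSet:
    """All Nx * Ny products of two one-dimensional families."""
    if basis_x.dim_reduced != 1 or basis_y.dim_reduced != 1:
        raise ValueError("tensor products require one-dimensional factors")
    return BasisSet(family="tensor_product", dim_reduced=2,
                    n_functions=basis_x.n_functions * basis_y.n_functions,
                    _impl=_TensorProduct2D(basis_x, basis_y))
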