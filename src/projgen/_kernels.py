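"""Numba-compiled scalar energy/gradient kernels and Euler-Maruyama drivers.

Each bundled potential is implemented once, as a scalar ``energy(x, params)``
and an in-place ``grad(x, params, out)`` pair.  Batch evaluators and the
integration drivers are generic over these kernels: numba specializes them per
potential at first call.  Parameters travel as a flat float64 array so that a
single compiled specialization serves all parameter values.
"""

import numpy as np
from numba import njit

DIVERGENCE_LIMIT = 1e6

# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck / harmonic:  V = 1/2 (ax x^2 + ay y^2),  params = (ax, ay)


@njit(cache=True)
def ou_energy(x, params):
    return 0.5 * (params[0] * x[0] * x[0] + params[1] * x[1] * x[1])


@njit(cache=True)
def ou_grad(x, params, out):
    out[0] = params[0] * x[0]
    out[1] = params[1] * x[1]


# ---------------------------------------------------------------------------
# Lemon slice:  V(r, phi) = cos(4 phi) + 1/cos(phi/2) + 10 (r-1)^2 + 1/r
# in Cartesian coordinates; infinite barriers at r -> 0 and phi -> +-pi.
# params unused (the four terms are fixed).


@njit(cache=True)
def lemon_energy(x, params):
    r = np.sqrt(x[0] * x[0] + x[1] * x[1])
    phi = np.arctan2(x[1], x[0])
    return np.cos(4.0 * phi) + 1.0 / np.cos(0.5 * phi) + 10.0 * (r - 1.0) ** 2 + 1.0 / r


@njit(cache=True)
def lemon_grad(x, params, out):
    r2 = x[0] * x[0] + x[1] * x[1]
    r = np.sqrt(r2)
    phi = np.arctan2(x[1], x[0])
    c = np.cos(0.5 * phi)
    # dV/dr and dV/dphi
    dvdr = 20.0 * (r - 1.0) - 1.0 / r2
    dvdphi = -4.0 * np.sin(4.0 * phi) + 0.5 * np.sin(0.5 * phi) / (c * c)
    # chain rule: grad r = (x, y)/r ; grad phi = (-y, x)/r^2
    out[0] = dvdr * x[0] / r - dvdphi * x[1] / r2
    out[1] = dvdr * x[1] / r + dvdphi * x[0] / r2


# ---------------------------------------------------------------------------
# Quartic double well:  V = a4 x^4 - a2 x^2 + a1 x + cy y^2
# params = (a4, a2, a1, cy)


@njit(cache=True)
def doublewell_energy(x, params):
    return (params[0] * x[0] ** 4 - params[1] * x[0] ** 2 + params[2] * x[0]
            + params[3] * x[1] ** 2)


@njit(cache=True)
def doublewell_grad(x, params, out):
    out[0] = 4.0 * params[0] * x[0] ** 3 - 2.0 * params[1] * x[0] + params[2]
    out[1] = 2.0 * params[3] * x[1]


# ---------------------------------------------------------------------------
# Five-atom chain in 3D (15-dim state): harmonic bonds and angles, cosine
# dihedrals.  params = (kb, r0, ka, theta0, A1, A2); dihedral 1 (atoms 0-3)
# is threefold A1 (1 + cos 3 phi), dihedral 2 (atoms 1-4) twofold
# A2 (1 - cos 2 phi), giving 3 x 2 = 6 metastable basins in the dihedral
# plane.  No nonbonded terms; rigid-body motion is unconstrained.


@njit(cache=True)
def _bond_acc(x, i, j, kb, r0, out):
    dx = x[3 * j] - x[3 * i]
    dy = x[3 * j + 1] - x[3 * i + 1]
    dz = x[3 * j + 2] - x[3 * i + 2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    e = 0.5 * kb * (r - r0) ** 2
    f = kb * (r - r0) / r
    out[3 * j] += f * dx
    out[3 * j + 1] += f * dy
    out[3 * j + 2] += f * dz
    out[3 * i] -= f * dx
    out[3 * i + 1] -= f * dy
    out[3 * i + 2] -= f * dz
    return e


@njit(cache=True)
def _angle_acc(x, i, j, k, ka, theta0, out):
    # angle at vertex j between bonds j->i and j->k
    ax = x[3 * i] - x[3 * j]
    ay = x[3 * i + 1] - x[3 * j + 1]
    az = x[3 * i + 2] - x[3 * j + 2]
    bx = x[3 * k] - x[3 * j]
    by = x[3 * k + 1] - x[3 * j + 1]
    bz = x[3 * k + 2] - x[3 * j + 2]
    na = np.sqrt(ax * ax + ay * ay + az * az)
    nb = np.sqrt(bx * bx + by * by + bz * bz)
    cos_t = (ax * bx + ay * by + az * bz) / (na * nb)
    if cos_t > 1.0:
        cos_t = 1.0
    if cos_t < -1.0:
        cos_t = -1.0
    theta = np.arccos(cos_t)
    e = 0.5 * ka * (theta - theta0) ** 2
    dV = ka * (theta - theta0)
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    if sin_t < 1e-8:
        sin_t = 1e-8
    # d(theta)/d(atom i) = -1/sin * d(cos)/d(atom i)
    c1 = -dV / sin_t
    gix = c1 * (bx / (na * nb) - cos_t * ax / (na * na))
    giy = c1 * (by / (na * nb) - cos_t * ay / (na * na))
    giz = c1 * (bz / (na * nb) - cos_t * az / (na * na))
    gkx = c1 * (ax / (na * nb) - cos_t * bx / (nb * nb))
    gky = c1 * (ay / (na * nb) - cos_t * by / (nb * nb))
    gkz = c1 * (az / (na * nb) - cos_t * bz / (nb * nb))
    out[3 * i] += gix
    out[3 * i + 1] += giy
    out[3 * i + 2] += giz
    out[3 * k] += gkx
    out[3 * k + 1] += gky
    out[3 * k + 2] += gkz
    out[3 * j] -= gix + gkx
    out[3 * j + 1] -= giy + gky
    out[3 * j + 2] -= giz + gkz
    return e


@njit(cache=True)
def dihedral_angle(x, a, b, c, d):
    """Signed dihedral for atoms a-b-c-d of a flattened 3D configuration."""
    b1x = x[3 * b] - x[3 * a]
    b1y = x[3 * b + 1] - x[3 * a + 1]
    b1z = x[3 * b + 2] - x[3 * a + 2]
    b2x = x[3 * c] - x[3 * b]
    b2y = x[3 * c + 1] - x[3 * b + 1]
    b2z = x[3 * c + 2] - x[3 * b + 2]
    b3x = x[3 * d] - x[3 * c]
    b3y = x[3 * d + 1] - x[3 * c + 1]
    b3z = x[3 * d + 2] - x[3 * c + 2]
    # n1 = b1 x b2, n2 = b2 x b3
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    sx = b1x * n2x + b1y * n2y + b1z * n2z
    cx = n1x * n2x + n1y * n2y + n1z * n2z
    return np.arctan2(nb2 * sx, cx)


@njit(cache=True)
def _dihedral_grad(x, a, b, c, d, g):
    """Gradient of the dihedral angle wrt the four atoms (Blondel-Karplus).

    Writes the 12 components into ``g`` in atom order a, b, c, d.
    """
    b1x = x[3 * b] - x[3 * a]
    b1y = x[3 * b + 1] - x[3 * a + 1]
    b1z = x[3 * b + 2] - x[3 * a + 2]
    b2x = x[3 * c] - x[3 * b]
    b2y = x[3 * c + 1] - x[3 * b + 1]
    b2z = x[3 * c + 2] - x[3 * b + 2]
    b3x = x[3 * d] - x[3 * c]
    b3y = x[3 * d + 1] - x[3 * c + 1]
    b3z = x[3 * d + 2] - x[3 * c + 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    n1sq = n1x * n1x + n1y * n1y + n1z * n1z
    n2sq = n2x * n2x + n2y * n2y + n2z * n2z
    nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    # d phi / d a = -|b2|/|n1|^2 n1 ; d phi / d d = |b2|/|n2|^2 n2
    fa = -nb2 / n1sq
    fd = nb2 / n2sq
    gax = fa * n1x
    gay = fa * n1y
    gaz = fa * n1z
    gdx = fd * n2x
    gdy = fd * n2y
    gdz = fd * n2z
    c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
    c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
    gbx = -(1.0 + c12) * gax + c32 * gdx
    gby = -(1.0 + c12) * gay + c32 * gdy
    gbz = -(1.0 + c12) * gaz + c32 * gdz
    gcx = c12 * gax - (1.0 + c32) * gdx
    gcy = c12 * gay - (1.0 + c32) * gdy
    gcz = c12 * gaz - (1.0 + c32) * gdz
    g[0] = gax
    g[1] = gay
    g[2] = gaz
    g[3] = gbx
    g[4] = gby
    g[5] = gbz
    g[6] = gcx
    g[7] = gcy
    g[8] = gcz
    g[9] = gdx
    g[10] = gdy
    g[11] = gdz


@njit(cache=True)
def chain5_energy(x, params):
    kb, r0, ka, theta0, A1, A2 = params[0], params[1], params[2], params[3], params[4], params[5]
    scratch = np.zeros(15)
    e = 0.0
    for i in range(4):
        e += _bond_acc(x, i, i + 1, kb, r0, scratch)
    for i in range(3):
        e += _angle_acc(x, i, i + 1, i + 2, ka, theta0, scratch)
    phi1 = dihedral_angle(x, 0, 1, 2, 3)
    phi2 = dihedral_angle(x, 1, 2, 3, 4)
    e += A1 * (1.0 + np.cos(3.0 * phi1))
    e += A2 * (1.0 - np.cos(2.0 * phi2))
    return e


@njit(cache=True)
def chain5_grad(x, params, out):
    kb, r0, ka, theta0, A1, A2 = params[0], params[1], params[2], params[3], params[4], params[5]
    for i in range(15):
        out[i] = 0.0
    for i in range(4):
        _bond_acc(x, i, i + 1, kb, r0, out)
    for i in range(3):
        _angle_acc(x, i, i + 1, i + 2, ka, theta0, out)
    g = np.empty(12)
    phi1 = dihedral_angle(x, 0, 1, 2, 3)
    _dihedral_grad(x, 0, 1, 2, 3, g)
    dV = -3.0 * A1 * np.sin(3.0 * phi1)
    for k in range(4):
        for m in range(3):
            out[3 * k + m] += dV * g[3 * k + m]
    phi2 = dihedral_angle(x, 1, 2, 3, 4)
    _dihedral_grad(x, 1, 2, 3, 4, g)
    dV = 2.0 * A2 * np.sin(2.0 * phi2)
    for k in range(4):
        for m in range(3):
            out[3 * (k + 1) + m] += dV * g[3 * k + m]


# ---------------------------------------------------------------------------
# Generic batch evaluators and Euler-Maruyama drivers


@njit(cache=True)
def batch_energy(energy, X, params):
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = energy(X[i], params)
    return out


@njit(cache=True)
def batch_grad(grad, X, params):
    n, d = X.shape
    out = np.empty((n, d))
    for i in range(n):
        grad(X[i], params, out[i])
    return out


@njit(cache=True)
def em_overdamped(grad, params, x0, dt, n_steps, burn_in, inv_gamma, noise_amp, seed):
    """Euler-Maruyama for dX = -(1/gamma) grad V dt + noise_amp dB.

    Returns (states, fail_step); states holds the post-burn-in path of
    n_steps - burn_in + 1 points, fail_step is -1 on success or the step
    index where the state diverged.
    """
    d = x0.shape[0]
    np.random.seed(seed)
    n_keep = n_steps - burn_in + 1
    out = np.empty((n_keep, d))
    x = x0.copy()
    g = np.empty(d)
    sq = np.sqrt(dt)
    k = 0
    if burn_in == 0:
        out[0] = x
        k = 1
    for step in range(1, n_steps + 1):
        grad(x, params, g)
        ok = True
        for i in range(d):
            x[i] = x[i] - inv_gamma * g[i] * dt + noise_amp * sq * np.random.standard_normal()
            if not np.isfinite(x[i]) or np.abs(x[i]) > DIVERGENCE_LIMIT:
                ok = False
        if not ok:
            return out[:k], step
        if step >= burn_in:
            out[k] = x
            k += 1
    return out, -1


@njit(cache=True)
def em_underdamped(grad, params, q0, p0, dt, n_steps, burn_in, gamma, noise_amp, seed):
    """Euler-Maruyama for dq = p dt, dp = (-grad V - gamma p) dt + noise_amp dB.

    States are stored as (q, p) rows of width 2 d.
    """
    d = q0.shape[0]
    np.random.seed(seed)
    n_keep = n_steps - burn_in + 1
    out = np.empty((n_keep, 2 * d))
    q = q0.copy()
    p = p0.copy()
    g = np.empty(d)
    sq = np.sqrt(dt)
    k = 0
    if burn_in == 0:
        out[0, :d] = q
        out[0, d:] = p
        k = 1
    for step in range(1, n_steps + 1):
        grad(q, params, g)
        ok = True
        for i in range(d):
            qn = q[i] + p[i] * dt
            p[i] = p[i] + (-g[i] - gamma * p[i]) * dt + noise_amp * sq * np.random.standard_normal()
            q[i] = qn
            if not (np.isfinite(q[i]) and np.isfinite(p[i])) or np.abs(q[i]) > DIVERGENCE_LIMIT:
                ok = False
        if not ok:
            return out[:k], step
        if step >= burn_in:
            out[k, :d] = q
            out[k, d:] = p
            k += 1
    return out, -1
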