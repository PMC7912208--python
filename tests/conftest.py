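"""Shared fixtures: simulated trajectories reused across the suite.

All trajectories are generated at import-free session scope with fixed seeds
so the suite is deterministic; sizes are scaled so each fixture costs seconds
while keeping enough rare-event statistics for the spectral assertions.
"""

import numpy as np
import pytest

from projgen import models as M


@pytest.fixture(scope="session")
def ou_model():
    return M.make_model("overdamped", M.ou_potential(1.0, 5.0), 1.0, 1.0)


@pytest.fixture(scope="session")
def ou_traj(ou_model):
    return M.simulate_em(ou_model, dt=1e-3, n_steps=500_000, seed=11)


@pytest.fixture(scope="session")
def lemon_model():
    return M.make_model("overdamped", M.lemon_slice_potential(), 1.0, 1.0)


@pytest.fixture(scope="session")
def lemon_traj(lemon_model):
    return M.simulate_em(lemon_model, dt=1e-3, n_steps=1_000_000, seed=42)


@pytest.fixture(scope="session")
def dw_ol_model():
    return M.make_model("overdamped", M.double_well_potential(), 0.4, 10.0)


@pytest.fixture(scope="session")
def dw_ul_model():
    return M.make_model("underdamped", M.double_well_potential(), 0.4, 10.0)


@pytest.fixture(scope="session")
def dw_ol_traj(dw_ol_model):
    return M.simulate_em(dw_ol_model, dt=1e-3, n_steps=2_000_000, seed=7)


@pytest.fixture(scope="session")
def dw_ul_traj(dw_ul_model):
    return M.simulate_em(dw_ul_model, dt=1e-3, n_steps=2_000_000, seed=107)


@pytest.fixture(scope="session")
def chain5_model():
    return M.make_model("overdamped", M.chain5_potential(), 1.0, 1.0)


@pytest.fixture(scope="session")
def chain5_traj(chain5_model):
    return M.simulate_em(chain5_model, dt=5e-3, n_steps=500_000, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def km_vs_nonrev_zmax():
    """Largest entrywise z-score of the same-sample difference between the
    Kramers-Moyal assembly at s = dt and the exact-parameter
    generator-application assembly, with block standard errors."""

    def compute(model, rc, basis, traj, n_blocks=50):
        from projgen import gedmd as G
        X = traj.states
        s = traj.dt
        Z = rc.value(X)
        J = rc.jacobian(X)
        D = Z[1:] - Z[:-1]
        Z0 = Z[:-1]
        Gr = basis.gradient(Z0)
        P = basis.evaluate(Z0)
        Hb = basis.hessian(Z0)
        DD = np.einsum("nm,nk->nmk", D, D)
        km = -np.einsum("ni,nj->nij",
                        np.einsum("nim,nm->ni", Gr, D) / s
                        + 0.5 / s * np.einsum("nimk,nmk->ni", Hb, DD), P)
        Lxi = G._generator_on_rc(model, X[:-1], rc, J[:-1])
        Ared = model.a_reduced(J[:-1])
        non = -np.einsum("ni,nj->nij",
                         np.einsum("nim,nm->ni", Gr, Lxi)
                         + 0.5 * np.einsum("nimk,nmk->ni", Hb, Ared), P)
        diff = km - non
        n = diff.shape[0]
        blocks = diff[: n // n_blocks * n_blocks].reshape(
            n_blocks, -1, *diff.shape[1:]).mean(axis=1)
        se = blocks.std(axis=0) / np.sqrt(n_blocks)
        z = np.abs(diff.mean(axis=0)) / np.where(se > 0, se, 1.0)
        z[se == 0] = 0.0
        return z.max()

    return compute
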