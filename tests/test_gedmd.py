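"""Galerkin assembly, generalized eigenproblem, timescales, offset scans."""

import numpy as np
import pytest

from projgen import basis as B
from projgen import coordinates as C
from projgen import gedmd as G
from projgen import models as M
from projgen.bound import galerkin_quadrature


@pytest.fixture(scope="module")
def ou_setup(ou_model, ou_traj):
    rc = C.coordinate_select([0], 2, name="x")
    basis = B.hermite_basis(5)
    return ou_model, ou_traj, rc, basis


def test_constant_function_has_zero_stiffness_row(ou_setup):
    model, traj, rc, basis = ou_setup
    sub = M.Trajectory(states=traj.states[:20_000], dt=traj.dt, seed=traj.seed)
    # derivatives act on the first index: the H_0 = const row vanishes exactly
    for assemble in (G.assemble_reversible, G.assemble_nonreversible):
        sys = assemble(sub, rc, basis, model)
        assert np.allclose(sys.stiffness[0, :], 0.0)
    # the symmetric (Dirichlet-form) estimator also has an exactly zero column
    assert np.allclose(G.assemble_reversible(sub, rc, basis, model).stiffness[:, 0], 0.0)


def test_reversible_stiffness_is_symmetric(lemon_traj, lemon_model):
    rc = C.polar_angle()
    basis = B.gaussian_basis(np.linspace(-2.8, 2.8, 15), 0.1)
    sub = M.Trajectory(states=lemon_traj.states[:200_000], dt=lemon_traj.dt, seed=0)
    sys = G.assemble_reversible(sub, rc, basis, lemon_model)
    assert np.allclose(sys.stiffness, sys.stiffness.T, atol=1e-14)
    assert np.allclose(sys.mass, sys.mass.T, atol=1e-14)


def test_reversible_and_nonreversible_agree_within_mc_error(ou_setup):
    """The Dirichlet-form and generator-application estimators are two
    empirical forms of the same bilinear form; on shared samples they agree
    entrywise within 3 Monte-Carlo standard errors."""
    model, traj, rc, basis = ou_setup
    X = traj.states[:100_000]
    sub = M.Trajectory(states=X, dt=traj.dt, seed=traj.seed)
    s_rev = G.assemble_reversible(sub, rc, basis, model).stiffness
    s_non = G.assemble_nonreversible(sub, rc, basis, model).stiffness
    # per-sample contributions for the standard error of the difference
    Z = rc.value(X)
    J = rc.jacobian(X)
    Ared = model.a_reduced(J)
    Gr = basis.gradient(Z)
    P = basis.evaluate(Z)
    Lxi = G._generator_on_rc(model, X, rc, J)
    Hb = basis.hessian(Z)
    n = X.shape[0]
    rev_terms = 0.5 * np.einsum("nia,nab,njb->nij", Gr, Ared, Gr)
    Lphi = (np.einsum("nim,nm->ni", Gr, Lxi)
            + 0.5 * np.einsum("nimk,nmk->ni", Hb, Ared))
    non_terms = -np.einsum("ni,nj->nij", Lphi, P)
    diff = rev_terms - non_terms
    # trajectory samples are autocorrelated: the standard error of the mean
    # difference comes from contiguous block means, not per-sample scatter
    nb = 50  # blocks of 2000 steps = 2 correlation times of the slow mode
    blocks = diff[: n // nb * nb].reshape(nb, -1, *diff.shape[1:]).mean(axis=1)
    se = blocks.std(axis=0) / np.sqrt(nb)
    gap = np.abs(s_rev - s_non)
    assert np.all(gap <= 3 * se + 1e-12)


def test_underdamped_position_rc_kills_diffusion_term(dw_ul_model, dw_ul_traj):
    """For position-only coordinates of underdamped dynamics the reduced
    diffusion vanishes and only the transport term p . grad_q xi remains."""
    rc = C.coordinate_select([0], 4, name="x")
    X = dw_ul_traj.states[:5000]
    J = rc.jacobian(X)
    assert np.allclose(dw_ul_model.a_reduced(J), 0.0)
    Lxi = G._generator_on_rc(dw_ul_model, X, rc, J)
    assert np.allclose(Lxi[:, 0], X[:, 2])  # p_x
    with pytest.raises(ValueError):
        G.assemble_reversible(dw_ul_traj, rc, B.hermite_basis(3), dw_ul_model)


def test_km_constant_coordinate_gives_zero_stiffness(ou_traj):
    rc = C.ReactionCoordinate(
        name="const", dim_full=2, dim_reduced=1,
        periodic_mask=np.zeros(1, bool),
        _value=lambda X: np.full((X.shape[0], 1), 0.3),
        _jacobian=lambda X: np.zeros((X.shape[0], 2, 1)))
    basis = B.gaussian_basis(np.linspace(-1, 1, 4), 0.5)
    sub = M.Trajectory(states=ou_traj.states[:10_000], dt=ou_traj.dt, seed=0)
    sys = G.assemble_km(sub, rc, basis, offset_s=ou_traj.dt)
    assert np.allclose(sys.stiffness, 0.0)


def test_km_offset_validation(ou_traj):
    basis = B.hermite_basis(3)
    rc = C.coordinate_select([0], 2)
    with pytest.raises(ValueError):
        G.assemble_km(ou_traj, rc, basis, offset_s=1.5e-3 * np.pi)
    with pytest.raises(ValueError):
        G.assemble_km(ou_traj, rc, basis, offset_s=ou_traj.dt * len(ou_traj) * 2)


def test_km_slowest_eigenvalue_consistent_at_small_offset(ou_setup):
    """KM-gEDMD at s = dt on OU data recovers the analytic slowest rate
    alpha_x / gamma = 1 within Monte-Carlo error."""
    model, traj, rc, basis = ou_setup
    sm = G.solve(G.assemble_km(traj, rc, basis, traj.dt), basis)
    om = np.delete(sm.eigenvalues, sm.stationary_index)
    assert abs(om[0] - 1.0) < 0.1


def test_km_converges_to_nonreversible_as_dt_halves(ou_model, km_vs_nonrev_zmax):
    """The KM assembly at s = dt matches the exact-parameter assembly up to
    an O(dt) bias that stays buried in the Monte-Carlo noise on the same
    sample set: the entrywise difference is within 3 block standard errors
    at dt and remains so when dt halves."""
    rc = C.coordinate_select([0], 2)
    basis = B.hermite_basis(5)
    for dt, steps in [(4e-3, 200_000), (2e-3, 400_000)]:
        traj = M.simulate_em(ou_model, dt=dt, n_steps=steps, seed=77)
        assert km_vs_nonrev_zmax(ou_model, rc, basis, traj) < 3.0


def test_solve_diagonal_system():
    basis = B.hermite_basis(3)
    sys = G.GalerkinSystem(stiffness=np.diag([0.0, 1.0, 5.0]), mass=np.eye(3),
                           estimator="reversible", offset=0.0, n_samples=1)
    sm = G.solve(sys, basis)
    assert np.allclose(sm.eigenvalues, [0.0, 1.0, 5.0])
    assert sm.stationary_index == 0
    assert np.allclose(sm.timescales, [1.0, 0.2])


def test_solve_rejects_rank_deficit():
    basis = B.hermite_basis(3)
    mass = np.diag([1.0, 1.0, 1e-14])
    sys = G.GalerkinSystem(stiffness=np.eye(3), mass=mass,
                           estimator="reversible", offset=0.0, n_samples=1)
    with pytest.raises(ValueError):
        G.solve(sys, basis, n_eigs=3)
    assert G.solve(sys, basis).rank == 2


def test_minmax_ordering_for_nested_bases(ou_model):
    """Ritz values decrease when the dictionary grows (nested spaces) and
    always upper-bound the analytic OU eigenvalues r alpha_x."""
    rc = C.coordinate_select([0], 2, name="x")
    om = {}
    for n in (5, 10):
        sm = galerkin_quadrature(ou_model, C.oscillating_rc(3), hermite_n=n,
                                 quad_order=60)
        om[n] = np.delete(sm.eigenvalues, sm.stationary_index)[:4]
    assert np.all(om[10] <= om[5] + 1e-6)
    assert np.all(om[10] >= np.arange(1, 5) - 1e-9)


def test_reversible_eigenvalues_real_nonnegative(lemon_traj, lemon_model):
    rc = C.polar_angle()
    basis = B.gaussian_basis(np.linspace(-2.8, 2.8, 15), 0.1)
    sm = G.solve(G.assemble_reversible(lemon_traj, rc, basis, lemon_model), basis)
    assert np.all(sm.eigenvalues > -1e-10)
    assert sm.discarded_imag == 0.0


def test_implied_timescales_and_warnings():
    basis = B.hermite_basis(3)
    sm = G.SpectralModel(eigenvalues=np.array([0.0, 0.5, 2.0]),
                         eigenvectors=np.eye(3), basis=basis)
    assert np.allclose(G.implied_timescales(sm), [2.0, 0.5])
    sm_bad = G.SpectralModel(eigenvalues=np.array([-0.2, 0.0, 0.5]),
                             eigenvectors=np.eye(3), basis=basis)
    with pytest.warns(UserWarning):
        t = G.implied_timescales(sm_bad)
    assert np.isnan(t[0]) and np.isclose(t[1], 2.0)


def test_offset_scan_zero_error_against_itself(ou_setup):
    model, traj, rc, basis = ou_setup
    s = traj.dt
    ref = G.solve(G.assemble_km(traj, rc, basis, s), basis)
    table = G.offset_scan(traj, rc, basis, [s], ref, n_timescales=2)
    assert np.allclose(table[["E_1", "E_2"]].to_numpy(), 0.0, atol=1e-12)
    assert (table["error"] == "").all()


def test_offset_scan_propagates_errors_without_aborting(ou_setup):
    model, traj, rc, basis = ou_setup
    ref = G.solve(G.assemble_reversible(traj, rc, basis, model), basis)
    table = G.offset_scan(traj, rc, basis, [traj.dt, 1.5e-3 * np.pi], ref,
                          n_timescales=1)
    assert table.shape[0] == 2
    assert table.loc[1, "error"] != ""
    assert np.isnan(table.loc[1, "t_1"])


def test_lemon_timescale_stable_under_doubling(lemon_traj, lemon_model):
    """Doubling the sample count moves t1 by less than 3 bootstrap standard
    errors."""
    rc = C.polar_angle()
    basis = B.gaussian_basis(np.linspace(-2.8, 2.8, 15), 0.1)

    def t1_of(states):
        sub = M.Trajectory(states=states, dt=lemon_traj.dt, seed=0)
        sm = G.solve(G.assemble_reversible(sub, rc, basis, lemon_model), basis)
        return sm.timescales[0]

    half = t1_of(lemon_traj.states[:len(lemon_traj) // 2])
    full = t1_of(lemon_traj.states)
    boots = G.bootstrap_timescales(lemon_traj, rc, basis, estimator="reversible",
                                   model=lemon_model, n_blocks=50, n_resamples=50,
                                   seed=1)
    se = np.nanstd(boots[:, 0])
    assert abs(full - half) < 3 * se


def test_generator_edmd_estimator_api(ou_setup):
    from sklearn.base import clone
    model, traj, rc, basis = ou_setup
    est = G.GeneratorEDMD(basis=basis, rc=rc, estimator="reversible", model=model)
    est2 = clone(est)
    est2.fit(traj)
    assert est2.eigenvalues_.shape[0] == est2.rank_
    assert np.all(np.diff(est2.eigenvalues_) >= 0)
    funs = est2.transform(np.linspace(-2, 2, 11))
    assert funs.shape == (11, est2.rank_)
    params = est2.get_params()
    assert params["estimator"] == "reversible"
    with pytest.raises(ValueError):
        G.GeneratorEDMD(basis=basis, rc=rc, estimator="km").fit(traj)
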