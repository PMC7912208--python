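"""Kramers-Moyal differences, binned coefficients, lemon-slice closed form."""

import numpy as np
import pytest

from projgen import coordinates as C
from projgen import models as M
from projgen.effective import (KramersMoyal, km_binned, km_differences,
                               lemon_effective_coefficients)


def test_km_differences_constant_coordinate(ou_traj):
    rc = C.ReactionCoordinate(
        name="const", dim_full=2, dim_reduced=1,
        periodic_mask=np.zeros(1, bool),
        _value=lambda X: np.full((X.shape[0], 1), 1.0),
        _jacobian=lambda X: np.zeros((X.shape[0], 2, 1)))
    Z, D = km_differences(ou_traj, rc, ou_traj.dt)
    assert np.all(D == 0)


def test_km_differences_wrap_at_seam():
    """A trajectory crossing the -pi/pi seam yields a small net angular
    displacement, not a ~2 pi jump."""
    phis = np.array([3.1, 3.13, -3.13, -3.1])
    states = np.column_stack([np.cos(phis), np.sin(phis)])
    traj = M.Trajectory(states=states, dt=1.0, seed=0)
    _, D = km_differences(traj, C.polar_angle(), 1.0)
    assert np.all(np.abs(D) < 0.1)


def test_km_differences_ou_conditional_mean(ou_model):
    """For the OU process the conditional mean of d_s xi / s at x = z is
    z (exp(-alpha s / gamma) - 1) / s: at z = 1, s = 0.5 this is
    exp(-0.5) - 1 over 0.5 = -0.7869."""
    traj = M.simulate_em(ou_model, dt=1e-3, n_steps=2_000_000, seed=31)
    rc = C.coordinate_select([0], 2)
    Z, D = km_differences(traj, rc, 0.5)
    sel = np.abs(Z[:, 0] - 1.0) < 0.05
    est = (D[sel, 0] / 0.5).mean()
    expected = (np.exp(-0.5) - 1.0) / 0.5
    # block standard error over contiguous chunks of the selected samples
    vals = D[sel, 0] / 0.5
    nb = 50
    se = vals[: len(vals) // nb * nb].reshape(nb, -1).mean(axis=1).std() / np.sqrt(nb)
    assert abs(est - expected) < 3 * se + 0.05  # bin-width bias allowance


def test_km_binned_deterministic_drift():
    """Pure drift data x_m = m c dt: the binned estimators give exactly
    b = c and a = c^2 s in every visited bin."""
    c, dt = 1.3, 0.01
    x = np.arange(3000) * c * dt
    traj = M.Trajectory(states=x[:, None], dt=dt, seed=0)
    rc = C.coordinate_select([0], 1)
    est = km_binned(km_differences(traj, rc, dt), dt, n_bins=10, min_count=10)
    ok = est.mask
    assert ok.sum() >= 8
    assert np.allclose(est.drift[ok, 0], c, rtol=1e-10)
    assert np.allclose(est.diffusion[ok, 0, 0], c ** 2 * dt, rtol=1e-10)


def test_km_binned_consistency_on_double_well(dw_ol_traj, dw_ol_model):
    """At s = dt the binned KM coefficients reproduce the exact drift
    -V'(x)/gamma and diffusion 2/(beta gamma) within Monte-Carlo error in
    well-populated bins."""
    rc = C.coordinate_select([0], 2)
    est = KramersMoyal(rc=rc, offset=dw_ol_traj.dt, n_bins=30,
                       min_count=5000).fit(dw_ol_traj)
    model = dw_ol_model
    z = est.bin_centers_[:, 0]
    bex = model.drift(np.column_stack([z, np.zeros_like(z)]))[:, 0]
    aex = model.diffusion_scale
    ok = est.mask_
    # the diffusion estimator concentrates fast; the drift has spread a/s
    se_b = np.sqrt(aex / dw_ol_traj.dt / est.counts_[ok])
    assert np.all(np.abs(est.drift_[ok, 0] - bex[ok]) < 4 * se_b)
    assert np.allclose(est.diffusion_[ok, 0, 0], aex, rtol=0.1)


def test_km_underdamped_coefficients_vanish_at_small_offset(dw_ul_traj, dw_ol_traj):
    """Position-only projections of underdamped dynamics have vanishing
    conditional-expectation coefficients: at s = dt the UL estimates are
    near zero while OL estimates are O(1)."""
    s = dw_ul_traj.dt
    ul = KramersMoyal(rc=C.coordinate_select([0], 4), offset=s,
                      n_bins=20, min_count=1000).fit(dw_ul_traj)
    ol = KramersMoyal(rc=C.coordinate_select([0], 2), offset=s,
                      n_bins=20, min_count=1000).fit(dw_ol_traj)
    a_ul = np.nanmedian(ul.diffusion_[:, 0, 0])
    a_ol = np.nanmedian(ol.diffusion_[:, 0, 0])
    assert a_ul < 0.05 * a_ol
    assert np.nanmax(np.abs(ul.drift_)) < 0.2 * np.nanmax(np.abs(ol.drift_))


def test_lemon_effective_diffusion_constant():
    b_xi, a_xi = lemon_effective_coefficients(1.0, 1.0)
    z = np.linspace(-3.0, 3.0, 301)
    a = a_xi(z)
    assert a.max() - a.min() < 1e-10
    assert a[0] > 0


def test_lemon_effective_drift_has_four_stable_zeros():
    """The effective drift crosses zero downward at the four minima of the
    angular potential."""
    b_xi, _ = lemon_effective_coefficients(1.0, 1.0)
    z = np.linspace(-np.pi + 0.05, np.pi - 0.05, 4001)
    b = b_xi(z)
    sign_change = np.where(np.diff(np.sign(b)) != 0)[0]
    descending = [i for i in sign_change if b[i] > 0 > b[i + 1]]
    assert len(descending) == 4


def test_lemon_effective_drift_integrates_to_zero():
    """b_xi is proportional to the derivative of an even periodic function:
    its symmetric integral vanishes."""
    b_xi, _ = lemon_effective_coefficients(1.0, 1.0)
    z = np.linspace(-np.pi + 0.05, np.pi - 0.05, 20001)
    integral = np.trapezoid(b_xi(z), z)
    assert abs(integral) < 1e-10


def test_lemon_quadrature_convergence_guard():
    with pytest.raises(RuntimeError):
        lemon_effective_coefficients(1.0, 1.0, quadrature_n=4)


def test_lemon_km_matches_analytic_at_small_offset(lemon_traj):
    """Binned KM diffusion at s = dt agrees with the radial-quadrature
    closed form; at s = 1.0 the estimate is visibly non-constant in the
    angle."""
    rc = C.polar_angle()
    _, a_xi = lemon_effective_coefficients(1.0, 1.0)
    a_exact = a_xi(np.array([0.0]))[0]
    small = KramersMoyal(rc=rc, offset=lemon_traj.dt, n_bins=30,
                         min_count=2000).fit(lemon_traj)
    ok = small.mask_
    a_small = small.diffusion_[ok, 0, 0]
    assert np.nanmax(np.abs(a_small - a_exact)) / a_exact < 0.1
    large = KramersMoyal(rc=rc, offset=1.0, n_bins=30, min_count=2000).fit(lemon_traj)
    a_large = large.diffusion_[large.mask_, 0, 0]
    rel_var_small = (a_small.max() - a_small.min()) / a_exact
    rel_var_large = (a_large.max() - a_large.min()) / a_exact
    assert rel_var_large > 3 * rel_var_small


def test_km_dual_meaning_timescale(dw_ol_traj, dw_ol_model):
    """The KM-gEDMD eigenvalues approximate the generator of the SDE whose
    coefficients are the binned KM estimates: simulating that effective
    1D SDE and fitting it with exact-parameter Galerkin matrices gives the
    same dominant timescale as the KM-gEDMD shortcut."""
    from projgen import basis as B
    from projgen import gedmd as G
    s = dw_ol_traj.dt
    rc = C.coordinate_select([0], 2)
    basis = B.gaussian_basis(np.linspace(-2.5, 2.5, 15), 0.1)
    sm_shortcut = G.solve(G.assemble_km(dw_ol_traj, rc, basis, s), basis,
                          mass_tol=1e-6)
    t_shortcut = np.delete(sm_shortcut.eigenvalues, sm_shortcut.stationary_index)[0]
    # tabulated effective coefficients
    est = KramersMoyal(rc=rc, offset=s, n_bins=40, min_count=500).fit(dw_ol_traj)
    ok = est.mask_
    zc, bv, av = est.bin_centers_[ok, 0], est.drift_[ok, 0], est.diffusion_[ok, 0, 0]
    rng = np.random.default_rng(5)
    n, dt = 1_000_000, 1e-3
    x = np.empty(n)
    x[0] = zc[np.argmin(np.abs(zc + 1))]
    noise = rng.standard_normal(n - 1)
    lo, hi = zc[0], zc[-1]
    for k in range(n - 1):
        b = np.interp(x[k], zc, bv)
        a = np.interp(x[k], zc, av)
        x[k + 1] = np.clip(x[k] + b * dt + np.sqrt(a * dt) * noise[k], lo, hi)
    eff = M.Trajectory(states=x[:, None], dt=dt, seed=5)
    # exact-parameter Galerkin matrices of the tabulated 1D SDE
    Z = eff.states
    P = basis.evaluate(Z)
    Gr = basis.gradient(Z)[:, :, 0]
    a_z = np.interp(Z[:, 0], zc, av)
    S = 0.5 * np.einsum("n,ni,nj->ij", a_z, Gr, Gr) / n
    Mm = P.T @ P / n
    sys1d = G.GalerkinSystem(stiffness=S, mass=Mm, estimator="reversible",
                             offset=0.0, n_samples=n)
    sm_eff = G.solve(sys1d, basis, mass_tol=1e-6)
    t_eff = np.delete(sm_eff.eigenvalues, sm_eff.stationary_index)[0]
    assert t_eff == pytest.approx(t_shortcut, rel=0.15)
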