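"""Finite elasticity: active-strain kinematics, mixed equilibrium
solves, stress/strain reductions, the staggered loop's trivial limits."""

import numpy as np
import pytest

from cardioem.geometry import FiberField, slab_mesh
from cardioem.mechanics import (ActiveStrain, DomainError,
                                EquilibriumSolver, Material, MechState,
                                active_tensor, build_p2, basal_bcs,
                                element_triads, gamma_from_cell,
                                stress_strain_magnitudes)

TRIAD = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
         np.array([0, 0, 1.0]))


# ------------------------------------------------------ active kinematics
def test_zero_gamma_gives_identity():
    np.testing.assert_array_equal(active_tensor(0.0, TRIAD), np.eye(3))


@pytest.mark.parametrize("gf", np.linspace(-0.24, -0.01, 8))
def test_active_tensor_volume_preserving(gf):
    # admissible fiber strains keep gamma_n = K gamma_f above -1
    f0 = active_tensor(ActiveStrain(gf, 4.0), TRIAD)
    assert abs(np.linalg.det(f0) - 1.0) < 1e-12


def test_gamma_below_admissible_range_rejected():
    with pytest.raises(DomainError):
        ActiveStrain(-0.3, 4.0)   # gamma_n would reach -1.2


def test_cross_fiber_strain_link():
    g = ActiveStrain(-0.1, 4.0)
    assert g.gamma_n == pytest.approx(-0.4)
    assert g.gamma_s == pytest.approx(1.0 / (0.9 * 0.6) - 1.0)


def test_gamma_domain_error():
    with pytest.raises(DomainError):
        ActiveStrain(-1.2)


def test_gamma_from_cell_substitution():
    sl = np.array([1.9, 1.71, 1.9])
    g = gamma_from_cell(sl, 1.9)
    assert g[0] == 0.0
    assert g[1] == pytest.approx(-0.1)


def test_gamma_negative_during_contraction(steady):
    """Unloaded twitches shorten: min gamma_f < 0, and the HFpEF cell
    shortens less than control."""
    tr_c, _ = steady("CONTROL", "EPI")
    tr_h, _ = steady("HFPEF", "EPI")
    gc = gamma_from_cell(tr_c["sl"], 1.9)
    gh = gamma_from_cell(tr_h["sl"], 1.9)
    assert gc.min() < 0 and gh.min() < 0
    assert abs(gh.min()) < abs(gc.min())


# ------------------------------------------------------------ equilibrium
@pytest.fixture(scope="module")
def cube():
    pts, tets, _ = slab_mesh(2, 2, 2, 1.0, 1.0, 1.0)
    p2 = build_p2(pts, tets)
    n = len(pts)
    fib = FiberField(np.tile([1.0, 0, 0], (n, 1)),
                     np.tile([0, 1.0, 0], (n, 1)),
                     np.tile([0, 0, 1.0], (n, 1)))
    triads = element_triads(fib, tets)
    i0 = int(np.argmin(np.linalg.norm(p2.points - [0, 0, 0], axis=1)))
    ix = int(np.argmin(np.linalg.norm(p2.points - [1, 0, 0], axis=1)))
    iy = int(np.argmin(np.linalg.norm(p2.points - [0, 1, 0], axis=1)))
    fixed = np.array([3 * i0, 3 * i0 + 1, 3 * i0 + 2, 3 * ix + 1,
                      3 * ix + 2, 3 * iy + 2])
    return pts, tets, p2, triads, fixed


def test_unloaded_reference_is_equilibrium(cube):
    pts, tets, p2, triads, fixed = cube
    solver = EquilibriumSolver(p2, triads, Material(), 4.0, fixed)
    st = solver.solve(np.zeros(len(pts)))
    assert np.abs(st.u).max() == 0.0
    assert np.abs(st.p).max() == 0.0
    assert st.residual_norm < 1e-12


def test_uniform_gamma_free_cube_incompressible(cube):
    """Free active contraction is homogeneous with F = F0, so
    det F = 1 within the penalty tolerance."""
    pts, tets, p2, triads, fixed = cube
    solver = EquilibriumSolver(p2, triads, Material(2.0, 2000.0), 4.0,
                               fixed)
    st = solver.solve(np.full(len(pts), -0.1), n_continuation=2)
    f0 = active_tensor(ActiveStrain(-0.1, 4.0), TRIAD)
    corner = int(np.argmin(np.linalg.norm(p2.points - [1, 1, 1],
                                          axis=1)))
    np.testing.assert_allclose(st.u[corner], np.diag(f0) - 1.0,
                               atol=1e-4)
    # homogeneous F = F0 has det F = det F0 = 1
    grad = np.diag(1.0 + st.u[corner])
    assert abs(np.linalg.det(grad) - 1.0) < 0.01


def test_stationarity_of_returned_state(cube):
    pts, tets, p2, triads, fixed = cube
    solver = EquilibriumSolver(p2, triads, Material(), 4.0, fixed)
    st = solver.solve(np.full(len(pts), -0.05))
    solver._residual_and_tangent(st.u.ravel(), st.p, st.gamma_vert)
    r = solver._resid.copy()
    r[solver.fixed] = 0.0
    assert np.linalg.norm(r) < 1e-8 * max(1.0, np.linalg.norm(st.u))


def test_stiffer_penalty_tightens_incompressibility(cube):
    """Doubling lambda shrinks max |J - 1| (here via the pressure-field
    magnitude that enforces ln J = p / lambda)."""
    pts, tets, p2, triads, fixed = cube
    devs = []
    for lam in (200.0, 2000.0):
        solver = EquilibriumSolver(p2, triads, Material(2.0, lam), 4.0,
                                   fixed)
        st = solver.solve(np.full(len(pts), -0.08), n_continuation=2)
        devs.append(np.abs(st.p / lam).max())   # |ln J| at equilibrium
    assert devs[1] < devs[0]


# --------------------------------------------------------------- fields
def _manual_state(p2, triads, u, p):
    n = len(p2.points)
    uu = np.zeros((n, 3))
    uu[:] = u(p2.points) if callable(u) else u
    return MechState(uu, p, p2, triads, np.zeros(p2.n_vert), 2.0,
                     2000.0, 4.0, 0.0, 0)


def test_zero_state_zero_fields(cube):
    pts, tets, p2, triads, _ = cube
    st = _manual_state(p2, triads, 0.0, np.zeros(p2.n_vert))
    vm, em = stress_strain_magnitudes(st)
    np.testing.assert_allclose(vm, 2.0 * 0, atol=1e-12)
    np.testing.assert_allclose(em, 0, atol=1e-12)


def test_hydrostatic_state_has_zero_von_mises(cube):
    pts, tets, p2, triads, _ = cube
    st = _manual_state(p2, triads, 0.0, np.full(p2.n_vert, 3.0))
    vm, _ = stress_strain_magnitudes(st)
    np.testing.assert_allclose(vm, 0, atol=1e-10)


def test_uniaxial_stretch_green_lagrange_norm(cube):
    """u = 0.1 x e_x: E = diag((1.1^2-1)/2, 0, 0), Frobenius norm
    0.105 by direct algebra."""
    pts, tets, p2, triads, _ = cube
    st = _manual_state(p2, triads,
                       lambda x: np.column_stack(
                           [0.1 * x[:, 0], 0 * x[:, 0], 0 * x[:, 0]]),
                       np.zeros(p2.n_vert))
    _, em = stress_strain_magnitudes(st)
    np.testing.assert_allclose(em, 0.5 * (1.1 ** 2 - 1.0), atol=1e-10)


# ----------------------------------------------------------- EM trivial
def test_run_em_without_stimulus_is_quiescent():
    from cardioem.mechanics import run_em

    r = run_em("NORMAL", "HFPEF", t_end=50.0, dt_mech=10.0, n_theta=12,
               n_long=6, n_trans=2, stimulate=False)
    assert r.ef == 0.0
    assert np.allclose(r.volumes, r.volumes[0])
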