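"""Tissue electrophysiology: conductivity tensor, transmural layout,
monodomain propagation and splitting accuracy."""

import math

import numpy as np
import pytest

import cardioem.constants as c
from cardioem.geometry import slab_mesh, lv_preset, rule_based_fibers
from cardioem.tissue import (BlockError, ConductivitySet, GeometryError,
                             MonodomainProblem, TransmuralLayout,
                             assign_cell_types, diffusion_tensor,
                             measure_cv, run_strand)


# ------------------------------------------------------ diffusion tensor
def test_isotropic_conductivity_gives_identity():
    cond = ConductivitySet(2.5, 2.5, 2.5)
    d = diffusion_tensor([1, 0, 0], [0, 1, 0], [0, 0, 1], cond)
    np.testing.assert_allclose(d, 2.5 * np.eye(3), atol=1e-14)


def test_eigenvalues_are_the_printed_conductivities():
    cond = ConductivitySet()
    d = diffusion_tensor([1, 0, 0], [0, 1, 0], [0, 0, 1], cond)
    assert d[0, 0] == 3.0
    ev = np.sort(np.linalg.eigvalsh(d))
    np.testing.assert_allclose(ev, sorted([3.0, 0.1, 0.31525]),
                               atol=1e-14)


def test_tensor_transforms_under_rotation():
    rng = np.random.default_rng(7)
    a = rng.normal(size=3)
    b = rng.normal(size=3)
    f = a / np.linalg.norm(a)
    s = b - np.dot(b, f) * f
    s /= np.linalg.norm(s)
    n = np.cross(f, s)
    cond = ConductivitySet()
    d = diffusion_tensor(f, s, n, cond)
    theta = 0.4
    rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                    [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
    d_rot = diffusion_tensor(rot @ f, rot @ s, rot @ n, cond)
    np.testing.assert_allclose(d_rot, rot @ d @ rot.T, atol=1e-12)


def test_non_orthonormal_triad_rejected():
    with pytest.raises(GeometryError):
        diffusion_tensor([1, 0, 0], [0.5, 0.5, 0], [0, 0, 1],
                         ConductivitySet())


# ------------------------------------------------------ transmural layout
def test_uniform_slab_splits_60_30_10():
    depth = np.linspace(0.0, 1.0, 2001)
    labels = assign_cell_types(depth)
    frac = {ct: np.mean(labels == ct) for ct in ("ENDO", "MCELL", "EPI")}
    assert frac["ENDO"] == pytest.approx(0.60, abs=0.03)
    assert frac["MCELL"] == pytest.approx(0.30, abs=0.03)
    assert frac["EPI"] == pytest.approx(0.10, abs=0.03)


def test_zero_depth_is_all_endo():
    labels = assign_cell_types(np.zeros(10))
    assert (labels == "ENDO").all()


def test_single_band_layout():
    layout = TransmuralLayout(((0.0, 1.0, "EPI"),))
    labels = assign_cell_types(np.linspace(0, 1, 11), layout)
    assert (labels == "EPI").all()


def test_depth_outside_unit_interval_rejected():
    with pytest.raises(GeometryError):
        assign_cell_types(np.array([-0.2, 0.5]))


def test_bad_layout_rejected():
    with pytest.raises(GeometryError):
        TransmuralLayout(((0.0, 0.5, "ENDO"), (0.6, 1.0, "EPI")))


# ---------------------------------------------------------- propagation
def test_control_strand_conducts_at_65_cm_s():
    cv = measure_cv(20.0, 0.1, dt=0.02)
    assert cv == pytest.approx(65.0, rel=0.05)


def test_cv_scales_as_sqrt_of_conductivity():
    cv1 = measure_cv(20.0, 0.1, dt=0.02)
    cv4 = run_strand(20.0, 0.1, dt=0.02, conductivity_factor=4.0).cv
    assert cv4 == pytest.approx(2.0 * cv1, rel=0.10)


def test_cv_grid_independence_at_fine_spacing():
    cva = run_strand(20.0, 0.125, dt=0.02).cv
    cvb = run_strand(20.0, 0.1, dt=0.02).cv
    assert abs(cva - cvb) / cvb < 0.03


def test_hfpef_fibrosis_slows_conduction_by_sqrt_08():
    cv_ctrl = measure_cv(20.0, 0.1, dt=0.02)
    cv_hf = run_strand(20.0, 0.1, dt=0.02, variant="HFPEF").cv
    assert cv_hf == pytest.approx(math.sqrt(0.8) * cv_ctrl, rel=0.05)


def test_zero_conductivity_blocks():
    with pytest.raises(BlockError):
        run_strand(20.0, 0.2, dt=0.02, conductivity_factor=0.0)


def test_short_strand_rejected():
    with pytest.raises(GeometryError):
        measure_cv(10.0, 0.2)


def test_strang_splitting_is_second_order():
    """Richardson step-halving on a 1D pulse: observed order ~ 2."""
    sols = {}
    for dt in (0.04, 0.02, 0.01):
        r = run_strand(10.0, 0.1, dt=dt, t_max=20.0, scheme=2,
                       record_v_at=18.0)
        sols[dt] = r.v_snapshot
    d1 = np.abs(sols[0.04] - sols[0.02]).max()
    d2 = np.abs(sols[0.02] - sols[0.01]).max()
    order = math.log2(d1 / d2)
    assert order > 1.6


# ------------------------------------------------------ mesh monodomain
def test_resting_tissue_diffusion_is_inert():
    """With no stimulus a spatially uniform layer evolves exactly like
    the space-clamped single cell: diffusion contributes nothing."""
    from cardioem.geometry import FiberField
    from cardioem.tissue import TransmuralLayout
    from cardioem.coupled import CoupledModel
    from cardioem.params import EpParams, MmParams
    from cardioem.state import initial_y

    pts, tets, depth = slab_mesh(2, 2, 2, 2.0, 2.0, 2.0)
    n = len(pts)
    fib = FiberField(np.tile([1.0, 0, 0], (n, 1)),
                     np.tile([0, 1.0, 0], (n, 1)),
                     np.tile([0, 0, 1.0], (n, 1)))
    layout = TransmuralLayout(((0.0, 1.0, "ENDO"),))
    # dt_diffusion = 4 dt makes the tissue reaction substep exactly the
    # single-cell step, so the comparison is roundoff-tight
    prob = MonodomainProblem(pts, tets, depth, fib, layout=layout,
                             dt=0.02, dt_diffusion=0.08)
    prob.run(10.0, np.zeros(n, bool))
    m = CoupledModel(EpParams().for_cell_type("ENDO"), MmParams(),
                     dt=0.02)
    y = initial_y("ENDO")
    m.run_interval(y, 10.0, stimulate=False)
    assert np.abs(prob.ystates[:, c.Y_V] - y[c.Y_V]).max() < 1e-6


def test_lv_mesh_fully_activates_before_200ms():
    """Three endocardial stimulus patches activate the whole coarse LV
    well before 200 ms."""
    from cardioem.tissue import default_stim_nodes, \
        activation_times_graph

    mesh = lv_preset("NORMAL", n_theta=12, n_long=6, n_trans=2)
    fib = rule_based_fibers(mesh)
    stim = default_stim_nodes(mesh, 14.0)
    act = activation_times_graph(mesh.points, mesh.tets, fib,
                                 ConductivitySet(), 65.0, 1.0,
                                 np.nonzero(stim)[0])
    assert np.isfinite(act).all()
    assert act.max() < 200.0
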