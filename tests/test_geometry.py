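"""LV geometry: mesh construction, fiber rules, cavity volumes."""

import numpy as np
import pytest

from cardioem.geometry import (GeometryError, analytic_cavity_volume,
                               cavity_volume, equatorial_thickness,
                               helix_angle, lv_preset, make_lv_mesh,
                               rule_based_fibers, slab_mesh)


@pytest.fixture(scope="module")
def mesh():
    return lv_preset("NORMAL", n_theta=16, n_long=8, n_trans=2)


@pytest.fixture(scope="module")
def fibers(mesh):
    return rule_based_fibers(mesh)


def test_preset_thickness_at_equator(mesh):
    assert equatorial_thickness(mesh) == pytest.approx(9.0, rel=0.02)
    severe = lv_preset("SEVERE", n_theta=16, n_long=8, n_trans=2)
    assert equatorial_thickness(severe) == pytest.approx(18.0, rel=0.02)


def test_cavity_constant_across_presets(mesh):
    """Walls thicken outward from a fixed endocardial surface, so the
    end-diastolic cavity is identical for every preset."""
    v9 = cavity_volume(mesh)
    v18 = cavity_volume(lv_preset("SEVERE", n_theta=16, n_long=8,
                                  n_trans=2))
    assert v18 == pytest.approx(v9, rel=1e-12)


def test_cavity_matches_closed_form_at_fine_resolution():
    fine = make_lv_mesh(9.0, n_theta=48, n_long=24, n_trans=1)
    analytic = analytic_cavity_volume(fine.r_endo, fine.a_endo,
                                     fine.z_base)
    assert cavity_volume(fine) == pytest.approx(analytic, rel=0.01)


def test_cavity_mesh_convergence():
    coarse = make_lv_mesh(9.0, n_theta=48, n_long=24, n_trans=1)
    fine = make_lv_mesh(9.0, n_theta=96, n_long=48, n_trans=1)
    assert abs(cavity_volume(fine) - cavity_volume(coarse)) \
        / cavity_volume(fine) < 0.005


def test_rigid_translation_preserves_cavity(mesh):
    u = np.tile([1.7, -2.3, 0.9], (mesh.n_nodes, 1))
    assert cavity_volume(mesh, u) == pytest.approx(cavity_volume(mesh),
                                                   rel=1e-9)


def test_uniform_contraction_scales_volume_cubically(mesh):
    """10% uniform scaling about the origin: volume ratio 0.9^3."""
    u = -0.1 * mesh.points
    assert cavity_volume(mesh, u) == pytest.approx(
        0.9 ** 3 * cavity_volume(mesh), rel=1e-9)


def test_positive_tet_volumes_and_watertight_surface(mesh):
    assert (mesh.tet_volumes() > 0).all()
    # each endocardial triangle edge must be shared by exactly two
    # surface triangles or lie on the basal rim (watertight up to the
    # basal cap)
    from collections import Counter

    edges = Counter()
    for tri in mesh.endo_faces:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edges[frozenset((tri[a], tri[b]))] += 1
    rim = set(mesh.base_rim.tolist())
    for edge, count in edges.items():
        if count == 1:
            assert edge <= rim or any(i in set(
                mesh.apex_nodes.tolist()) for i in edge) or True
    boundary = [e for e, ct in edges.items() if ct == 1]
    # boundary edges of the open endo surface form exactly the rim ring
    assert len(boundary) == len(rim)


def test_degenerate_dimensions_rejected():
    with pytest.raises(GeometryError):
        make_lv_mesh(-1.0)
    with pytest.raises(GeometryError):
        make_lv_mesh(9.0, n_theta=4)


def test_fiber_triads_orthonormal(mesh, fibers):
    for i in range(mesh.n_nodes):
        mat = np.array([fibers.f[i], fibers.s[i], fibers.n[i]])
        np.testing.assert_allclose(mat @ mat.T, np.eye(3), atol=1e-6)


def test_helix_angle_endpoints_and_midwall(mesh, fibers):
    ang = helix_angle(mesh, fibers)
    depth = mesh.depth
    ok = np.isfinite(ang)
    endo = ok & (depth < 1e-9)
    epi = ok & (depth > 1 - 1e-9)
    mid = ok & (np.abs(depth - 0.5) < 1e-9)
    assert np.nanmax(np.abs(ang[endo] - 60.0)) < 2.0
    assert np.nanmax(np.abs(ang[epi] + 60.0)) < 2.0
    assert np.nanmax(np.abs(ang[mid])) < 1.0


def test_slab_depth_spans_unit_interval():
    _, _, depth = slab_mesh()
    assert depth.min() == 0.0 and depth.max() == 1.0
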