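"""Left-ventricle geometry: truncated-ellipsoid tetrahedral meshes,
rule-based fiber architecture and cavity volumes.

The LV is a truncated prolate ellipsoid: the endocardial surface is held
fixed across the wall-thickness presets (NORMAL 9 mm, MILD 12 mm,
MODERATE 15 mm, SEVERE 18 mm) and the wall thickens outward, so the
end-diastolic cavity is identical for every degree of concentric
hypertrophy.  Meshes are built from a structured (transmural x
longitudinal x circumferential) hexahedral grid subdivided into
tetrahedra with the Kuhn scheme (face-diagonal compatible across
neighbours, including the circumferential wrap); the apex layer
collapses to wedges whose degenerate tetrahedra are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

THICKNESS_PRESETS = {"NORMAL": 9.0, "MILD": 12.0, "MODERATE": 15.0,
                     "SEVERE": 18.0}


class GeometryError(ValueError):
    pass


@dataclass
class LvMesh:
    """Tetrahedral truncated-ellipsoid left ventricle.

    Lengths in mm.  ``depth`` is the normalised transmural coordinate
    (0 = endocardium, 1 = epicardium); ``endo_faces`` are oriented
    triangles of the endocardial surface; ``base_rim`` the ordered node
    ring where the endocardium meets the basal plane.
    """

    points: np.ndarray            # (n_nodes, 3)
    tets: np.ndarray              # (n_tets, 4)
    depth: np.ndarray             # (n_nodes,)
    endo_faces: np.ndarray        # (n_faces, 3)
    base_rim: np.ndarray          # (n_rim,)
    base_nodes: np.ndarray        # node ids on the basal plane
    apex_nodes: np.ndarray        # collapsed apex node ids
    thickness: float
    r_endo: float
    a_endo: float
    z_base: float
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def tet_volumes(self) -> np.ndarray:
        p = self.points
        a = p[self.tets[:, 1]] - p[self.tets[:, 0]]
        b = p[self.tets[:, 2]] - p[self.tets[:, 0]]
        d = p[self.tets[:, 3]] - p[self.tets[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), d) / 6.0


@dataclass
class FiberField:
    """Per-node orthonormal fiber / sheet / sheet-normal triads."""

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray


def _kuhn_tets():
    """Six-tetrahedron Kuhn subdivision of the unit hexahedron, as
    corner triples in binary (x, y, z) coordinates."""
    import itertools

    tets = []
    for perm in itertools.permutations(range(3)):
        v = [np.zeros(3, int)]
        for ax in perm:
            nxt = v[-1].copy()
            nxt[ax] = 1
            v.append(nxt)
        tets.append(np.array(v))
    return tets


_KUHN = _kuhn_tets()


def make_lv_mesh(thickness_mm: float = 9.0, r_endo: float = 24.0,
                 a_endo: float = 68.0, z_base_frac: float = 0.5,
                 n_theta: int = 16, n_long: int = 8,
                 n_trans: int = 2) -> LvMesh:
    """Build a truncated-ellipsoid LV mesh.

    The endocardial surface has equatorial radius ``r_endo`` and apical
    half-axis ``a_endo``; the base plane sits at ``z_base_frac *
    a_endo`` above the equator and the apex points toward -z.  The wall
    is offset outward by ``thickness_mm`` (exact at the equator).
    """
    if thickness_mm <= 0 or r_endo <= 0 or a_endo <= 0:
        raise GeometryError("degenerate LV dimensions")
    if n_trans < 1 or n_long < 2 or n_theta < 6:
        raise GeometryError("resolution too coarse for an LV mesh")
    z_base = z_base_frac * a_endo
    t = thickness_mm

    def radius(xi):
        return r_endo + xi * t

    def axis(xi):
        return a_endo + xi * t

    # node table: rings for s in [0, n_long), one apex node per xi layer
    node_id = {}
    points = []
    depth = []
    param = []   # (xi, s_frac, theta_index or -1 for apex)

    def add_node(key, xyz, xi, sfrac, itheta):
        node_id[key] = len(points)
        points.append(xyz)
        depth.append(xi)
        param.append((xi, sfrac, itheta))

    for ix in range(n_trans + 1):
        xi = ix / n_trans
        rho, ax = radius(xi), axis(xi)
        ub = math.acos(min(z_base / ax, 1.0))
        for isl in range(n_long):
            sfrac = isl / n_long
            u = ub + sfrac * (math.pi - ub)
            for it in range(n_theta):
                th = 2.0 * math.pi * it / n_theta
                xyz = (rho * math.sin(u) * math.cos(th),
                       rho * math.sin(u) * math.sin(th),
                       ax * math.cos(u))
                add_node((ix, isl, it), xyz, xi, sfrac, it)
        # apex
        add_node((ix, n_long, 0), (0.0, 0.0, -ax), xi, 1.0, -1)

    points = np.asarray(points)
    depth = np.asarray(depth)

    def nid(ix, isl, it):
        if isl == n_long:
            return node_id[(ix, n_long, 0)]
        return node_id[(ix, isl, it % n_theta)]

    # hexes -> Kuhn tets (degenerate apex tets dropped)
    tets = []
    for ix in range(n_trans):
        for isl in range(n_long):
            for it in range(n_theta):
                corner = {}
                for bx in (0, 1):
                    for by in (0, 1):
                        for bz in (0, 1):
                            # x: transmural, y: longitudinal, z: circum
                            corner[(bx, by, bz)] = nid(ix + bx, isl + by,
                                                       it + bz)
                for kt in _KUHN:
                    ids = [corner[tuple(vv)] for vv in kt]
                    if len(set(ids)) == 4:
                        tets.append(ids)
    tets = np.asarray(tets)

    # orient all tets positively
    mesh = LvMesh(points, tets, depth, np.empty((0, 3), int),
                  np.empty(0, int), np.empty(0, int), np.empty(0, int),
                  thickness_mm, r_endo, a_endo, z_base)
    vol = mesh.tet_volumes()
    flip = vol < 0
    tets[flip, 0], tets[flip, 1] = (tets[flip, 1].copy(),
                                    tets[flip, 0].copy())
    mesh.tets = tets
    if (mesh.tet_volumes() <= 0).any():
        raise GeometryError("mesh contains degenerate tetrahedra")

    # endocardial surface triangles: tet faces whose nodes all lie on
    # the xi=0 layer, oriented outward from the myocardium (into the
    # cavity normal handled by cavity_volume via a consistent sweep)
    on_endo = depth < 1e-12
    faces = []
    for tet in tets:
        mask = on_endo[tet]
        if mask.sum() == 3:
            tri = tet[mask]
            opp = tet[~mask][0]
            # orient so the normal points away from the interior node
            a, b, cc = (points[i] for i in tri)
            nrm = np.cross(b - a, cc - a)
            if np.dot(nrm, points[opp] - a) > 0:
                tri = tri[[0, 2, 1]]
            faces.append(tri)
    endo_faces = np.asarray(faces)

    base_nodes = np.nonzero(np.abs(points[:, 2] - z_base) < 1e-9)[0]
    rim = [nid(0, 0, it) for it in range(n_theta)]
    apex = np.array([node_id[(ix, n_long, 0)]
                     for ix in range(n_trans + 1)])
    mesh.endo_faces = endo_faces
    mesh.base_rim = np.asarray(rim)
    mesh.base_nodes = base_nodes
    mesh.apex_nodes = apex
    mesh.meta = {"n_theta": n_theta, "n_long": n_long, "n_trans": n_trans,
                 "z_base_frac": z_base_frac}
    return mesh


def lv_preset(name: str, **kwargs) -> LvMesh:
    """Build one of the named wall-thickness presets."""
    if name not in THICKNESS_PRESETS:
        raise GeometryError(
            f"unknown preset {name!r}; valid: {list(THICKNESS_PRESETS)}")
    return make_lv_mesh(THICKNESS_PRESETS[name], **kwargs)


def equatorial_thickness(mesh: LvMesh) -> float:
    """Wall thickness measured on the equatorial plane (z = 0),
    interpolating each surface's radius-vs-height profile."""
    pts = mesh.points

    def r_at_equator(surface_mask):
        z = pts[surface_mask, 2]
        r = np.hypot(pts[surface_mask, 0], pts[surface_mask, 1])
        order = np.argsort(z)
        return float(np.interp(0.0, z[order], r[order]))

    r_in = r_at_equator(mesh.depth < 1e-12)
    r_out = r_at_equator(mesh.depth > 1 - 1e-12)
    return r_out - r_in


# ---------------------------------------------------------------- fibers
def rule_based_fibers(mesh: LvMesh, endo_angle: float = 60.0,
                      epi_angle: float = -60.0) -> FiberField:
    """Rule-based fiber architecture.

    The fiber helix angle rotates linearly with transmural depth from
    ``endo_angle`` (endocardium) to ``epi_angle`` (epicardium) about the
    local circumferential direction; the sheet direction is transmural
    and the sheet-normal completes the right-handed orthonormal triad.
    """
    pts = mesh.points
    n = len(pts)
    f = np.zeros((n, 3))
    s = np.zeros((n, 3))
    nn = np.zeros((n, 3))
    apex = set(mesh.apex_nodes.tolist())
    zhat = np.array([0.0, 0.0, 1.0])
    for i in range(n):
        if i in apex:
            # circumferential direction is singular at the apex; use a
            # fixed triad with transmural sheet along -z
            f[i] = (1.0, 0.0, 0.0)
            s[i] = (0.0, 0.0, -1.0)
            nn[i] = np.cross(f[i], s[i])
            continue
        p = pts[i]
        e_c = np.array([-p[1], p[0], 0.0])
        e_c /= np.linalg.norm(e_c)
        # transmural direction: outward from the local ellipsoid surface
        xi = mesh.depth[i]
        rho = mesh.r_endo + xi * mesh.thickness
        ax = mesh.a_endo + xi * mesh.thickness
        grad = np.array([2 * p[0] / rho ** 2, 2 * p[1] / rho ** 2,
                         2 * p[2] / ax ** 2])
        e_t = grad / np.linalg.norm(grad)
        # longitudinal (toward base), orthonormal completion
        e_l = np.cross(e_c, e_t)
        e_l /= np.linalg.norm(e_l)
        alpha = math.radians(endo_angle
                             + (epi_angle - endo_angle) * xi)
        fi = math.cos(alpha) * e_c + math.sin(alpha) * e_l
        si = e_t - np.dot(e_t, fi) * fi
        si /= np.linalg.norm(si)
        f[i] = fi
        s[i] = si
        nn[i] = np.cross(fi, si)
    return FiberField(f, s, nn)


def helix_angle(mesh: LvMesh, fibers: FiberField) -> np.ndarray:
    """Recovered helix angle (deg) of each node's fiber vector."""
    pts = mesh.points
    out = np.full(len(pts), np.nan)
    for i, p in enumerate(pts):
        e_c = np.array([-p[1], p[0], 0.0])
        nc = np.linalg.norm(e_c)
        if nc < 1e-9:
            continue
        e_c /= nc
        fi = fibers.f[i]
        long_comp = fi - np.dot(fi, e_c) * e_c
        out[i] = math.degrees(math.atan2(np.linalg.norm(long_comp)
                                         * np.sign(np.dot(long_comp,
                                                          _e_l(mesh, i))),
                                         np.dot(fi, e_c)))
    return out


def _e_l(mesh, i):
    p = mesh.points[i]
    e_c = np.array([-p[1], p[0], 0.0])
    e_c /= np.linalg.norm(e_c)
    xi = mesh.depth[i]
    rho = mesh.r_endo + xi * mesh.thickness
    ax = mesh.a_endo + xi * mesh.thickness
    grad = np.array([2 * p[0] / rho ** 2, 2 * p[1] / rho ** 2,
                     2 * p[2] / ax ** 2])
    e_t = grad / np.linalg.norm(grad)
    e_l = np.cross(e_c, e_t)
    return e_l / np.linalg.norm(e_l)


# --------------------------------------------------------- cavity volume
def cavity_volume(mesh: LvMesh, u: np.ndarray | None = None) -> float:
    """Cavity volume (mL) enclosed by the (deformed) endocardial surface
    closed by a basal-plane cap, via the divergence theorem."""
    if len(mesh.endo_faces) == 0:
        raise GeometryError("mesh has no endocardial surface")
    pts = mesh.points.copy()
    if u is not None:
        pts = pts + u
    vol6 = 0.0
    for tri in mesh.endo_faces:
        a, b, cc = pts[tri[0]], pts[tri[1]], pts[tri[2]]
        vol6 += np.dot(a, np.cross(b, cc))
    # basal cap: fan around the deformed rim centroid, oriented to match
    # the (inward-facing) endocardial triangles
    rim = pts[mesh.base_rim]
    ctr = rim.mean(axis=0)
    nrim = len(rim)
    for i in range(nrim):
        a, b = rim[i], rim[(i + 1) % nrim]
        vol6 += np.dot(ctr, np.cross(b, a))
    return abs(vol6) / 6.0 / 1000.0   # mm^3 -> mL


def analytic_cavity_volume(r_endo: float, a_endo: float,
                           z_base: float) -> float:
    """Closed-form truncated-ellipsoid cavity volume (mL): solid of
    revolution of the ellipse from the apex (z=-a) to the base plane."""
    zeta = z_base / a_endo
    # V = pi r^2 a [ (zeta - zeta^3/3) + 2/3 ]
    v = math.pi * r_endo ** 2 * a_endo * ((zeta - zeta ** 3 / 3.0)
                                          + 2.0 / 3.0)
    return v / 1000.0


# ------------------------------------------------------ fixture meshes
def strand_mesh(length_mm: float = 20.0, dx: float = 0.2) -> np.ndarray:
    """1D strand node coordinates (mm)."""
    n = int(round(length_mm / dx)) + 1
    return np.linspace(0.0, length_mm, n)


def slab_mesh(nx: int = 4, ny: int = 4, nz: int = 4,
              lx: float = 4.0, ly: float = 4.0, lz: float = 4.0):
    """Structured tetrahedral slab; transmural depth spans [0, 1] along
    z.  Returns (points, tets, depth)."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    pid = lambda i, j, kk: (i * (ny + 1) + j) * (nz + 1) + kk
    pts = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    tets = []
    for i in range(nx):
        for j in range(ny):
            for kk in range(nz):
                corner = {(bx, by, bz): pid(i + bx, j + by, kk + bz)
                          for bx in (0, 1) for by in (0, 1)
                          for bz in (0, 1)}
                for kt in _KUHN:
                    tets.append([corner[tuple(vv)] for vv in kt])
    tets = np.asarray(tets)
    depth = pts[:, 2] / lz
    return pts, tets, depth
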