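"""Active-strain finite elasticity of the left ventricle.

The deformation gradient is decomposed multiplicatively, F = Fe F0, with
the active part built from the fiber triad:

    F0 = I + gamma_f f x f + gamma_s s x s + gamma_n n x n
    gamma_n = K gamma_f,   gamma_s = 1/((1+gamma_f)(1+gamma_n)) - 1

so det F0 = 1 identically; gamma_f = (SL - SL0)/SL0 is driven by the
sarcomere shortening of the electromechanical cell model (gamma < 0 is
contraction).  Quasi-static equilibria of the mixed neo-Hookean energy
are found with Newton's method on P2 displacement / P1 pressure
tetrahedra; the basal plane is constrained longitudinally with two
in-plane pins, all other surfaces are traction-free (no cavity
pressure is applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _mech_kernels as mk
from .geometry import (LvMesh, FiberField, lv_preset, rule_based_fibers,
                       cavity_volume, GeometryError, THICKNESS_PRESETS)


class SolverError(RuntimeError):
    pass


class DomainError(ValueError):
    pass


# ----------------------------------------------------------- active strain
@dataclass
class ActiveStrain:
    """Fiber / sheet / cross-sheet active strains with the
    microscopic-macroscopic link parameter K (default 4)."""

    gamma_f: float
    k: float = 4.0

    def __post_init__(self):
        if self.gamma_f <= -1.0 or self.gamma_f >= 1.0:
            raise DomainError("gamma_f must lie in (-1, 1)")
        if 1.0 + self.k * self.gamma_f <= 0.0:
            raise DomainError(
                f"gamma_n = K gamma_f = {self.k * self.gamma_f:.3f} "
                "must stay above -1 (gamma_f > -1/K)")

    @property
    def gamma_n(self) -> float:
        return self.k * self.gamma_f

    @property
    def gamma_s(self) -> float:
        return 1.0 / ((1.0 + self.gamma_f) * (1.0 + self.gamma_n)) - 1.0


def active_tensor(gamma, triad) -> np.ndarray:
    """F0 = I + gamma_f f x f + gamma_s s x s + gamma_n n x n.

    ``gamma`` is an :class:`ActiveStrain` (or a bare gamma_f, K = 4);
    det F0 = 1 exactly by the gamma_s construction.
    """
    if not isinstance(gamma, ActiveStrain):
        gamma = ActiveStrain(float(gamma))
    f, s, n = (np.asarray(v, float) for v in triad)
    for a, b in ((f, s), (f, n), (s, n)):
        if abs(np.dot(a, b)) > 1e-6:
            raise GeometryError("triad is not orthonormal")
    return (np.eye(3) + gamma.gamma_f * np.outer(f, f)
            + gamma.gamma_s * np.outer(s, s)
            + gamma.gamma_n * np.outer(n, n))


def gamma_from_cell(sl_trace: np.ndarray, sl0: float) -> np.ndarray:
    """Fiber active strain gamma_f(t) = (SL(t) - SL0)/SL0 from a
    sarcomere-length trace (gamma < 0 during contraction)."""
    sl_trace = np.asarray(sl_trace, float)
    if (sl_trace <= 0).any() or sl0 <= 0:
        raise DomainError("sarcomere lengths must be positive")
    return (sl_trace - sl0) / sl0


# ------------------------------------------------------------- P2 meshing
@dataclass
class P2Mesh:
    """Quadratic tetrahedral mesh derived from a linear one."""

    points: np.ndarray        # vertex + edge-midpoint coordinates
    conn10: np.ndarray        # (nel, 10): 4 vertices + 6 edge nodes
    vconn: np.ndarray         # (nel, 4) vertex connectivity
    n_vert: int
    dlams: np.ndarray         # (nel, 4, 3) barycentric gradients
    vols: np.ndarray          # (nel,)

    @property
    def n_nodes(self) -> int:
        return len(self.points)


def build_p2(points: np.ndarray, tets: np.ndarray) -> P2Mesh:
    points = np.asarray(points, float)
    tets = np.asarray(tets)
    edge_id = {}
    mid_pts = []
    nv = len(points)
    conn10 = np.empty((len(tets), 10), dtype=np.int64)
    for e, tet in enumerate(tets):
        conn10[e, :4] = tet
        for le, (a, b) in enumerate(mk.EDGE_LOCAL):
            key = (min(tet[a], tet[b]), max(tet[a], tet[b]))
            if key not in edge_id:
                edge_id[key] = nv + len(mid_pts)
                mid_pts.append(0.5 * (points[key[0]] + points[key[1]]))
            conn10[e, 4 + le] = edge_id[key]
    all_pts = np.vstack([points, np.asarray(mid_pts)]) if mid_pts \
        else points.copy()
    dlams = np.empty((len(tets), 4, 3))
    vols = np.empty(len(tets))
    for e, tet in enumerate(tets):
        mat = np.hstack([np.ones((4, 1)), points[tet]])
        inv = np.linalg.inv(mat)
        dlams[e] = inv[1:, :].T
        vols[e] = abs(np.linalg.det(mat)) / 6.0
    return P2Mesh(all_pts, conn10, tets.copy(), nv, dlams, vols)


def element_triads(fibers: FiberField, vconn: np.ndarray) -> np.ndarray:
    """Per-element orthonormal triads (vertex average, re-orthonormalised)."""
    nel = len(vconn)
    triads = np.empty((nel, 3, 3))
    for e, tet in enumerate(vconn):
        f = fibers.f[tet].mean(axis=0)
        s = fibers.s[tet].mean(axis=0)
        f /= np.linalg.norm(f)
        s -= np.dot(s, f) * f
        s /= np.linalg.norm(s)
        triads[e, 0] = f
        triads[e, 1] = s
        triads[e, 2] = np.cross(f, s)
    return triads


# ------------------------------------------------------------- mech state
@dataclass
class MechState:
    """Converged equilibrium: displacement over P2 nodes, pressure over
    vertices, plus the data needed to evaluate stresses."""

    u: np.ndarray             # (n_p2, 3)
    p: np.ndarray             # (n_vert,)
    p2: P2Mesh
    triads: np.ndarray
    gamma_vert: np.ndarray
    mu: float
    lam: float
    kappa: float
    residual_norm: float
    newton_iters: int

    @property
    def u_vert(self) -> np.ndarray:
        return self.u[:self.p2.n_vert]


@dataclass
class Material:
    """Nearly incompressible neo-Hookean constants (kPa)."""

    mu: float = 2.0
    lam: float = 2000.0


class EquilibriumSolver:
    """Newton solver for the mixed two-field equilibrium problem."""

    def __init__(self, p2: P2Mesh, triads: np.ndarray,
                 material: Material = Material(), kappa: float = 4.0,
                 fixed_dofs: np.ndarray | None = None):
        self.p2 = p2
        self.triads = triads
        self.mat = material
        self.kappa = kappa
        self.nu = 3 * p2.n_nodes
        self.ndof = self.nu + p2.n_vert
        self.fixed = np.zeros(self.ndof, bool)
        if fixed_dofs is not None:
            self.fixed[fixed_dofs] = True
        nel = len(p2.conn10)
        self._rows = np.zeros(nel * 34 * 34, dtype=np.int64)
        self._cols = np.zeros(nel * 34 * 34, dtype=np.int64)
        self._vals = np.zeros(nel * 34 * 34)
        self._resid = np.zeros(self.ndof)

    def _residual_and_tangent(self, u_flat, p_vec, gamma_vert):
        self._vals[:] = 0.0
        n_bad = mk.assemble(self.p2.conn10, self.p2.vconn, self.p2.dlams,
                            self.p2.vols, self.triads, self.kappa,
                            u_flat, p_vec, gamma_vert, self.mat.mu,
                            self.mat.lam, self._rows, self._cols,
                            self._vals, self._resid)
        return n_bad

    def solve(self, gamma_vert: np.ndarray,
              u0: np.ndarray | None = None,
              p0: np.ndarray | None = None,
              tol: float = 1e-8, max_iter: int = 30,
              n_continuation: int = 1) -> MechState:
        """Solve equilibrium for the given vertex gamma_f field.

        ``tol`` is relative to the residual of the first iterate (with
        an absolute floor); warm starts via ``u0``/``p0``.  If Newton
        fails, the load is applied in ``n_continuation`` increments
        (doubling on failure up to 8)."""
        gamma_vert = np.asarray(gamma_vert, float)
        if (gamma_vert <= -1.0).any():
            raise DomainError("gamma_f must stay above -1")
        u = np.zeros(self.nu) if u0 is None else u0.ravel().copy()
        p = np.zeros(self.p2.n_vert) if p0 is None else p0.copy()
        ncont = n_continuation
        while True:
            try:
                u_try, p_try, rn, iters = self._solve_ramped(
                    gamma_vert, u.copy(), p.copy(), tol, max_iter, ncont)
                break
            except SolverError:
                if ncont >= 8:
                    raise
                ncont *= 2
        return MechState(u_try.reshape(-1, 3), p_try, self.p2,
                         self.triads, gamma_vert, self.mat.mu,
                         self.mat.lam, self.kappa, rn, iters)

    def _solve_ramped(self, gamma_vert, u, p, tol, max_iter, ncont):
        total_iters = 0
        for inc in range(1, ncont + 1):
            g = gamma_vert * (inc / ncont)
            u, p, rn, it = self._newton(g, u, p, tol, max_iter)
            total_iters += it
        return u, p, rn, total_iters

    def _newton(self, gamma_vert, u, p, tol, max_iter):
        scale = None
        history = []
        for it in range(max_iter):
            n_bad = self._residual_and_tangent(u, p, gamma_vert)
            if n_bad:
                raise SolverError(
                    f"inverted element during assembly ({n_bad} bad)")
            r = self._resid.copy()
            r[self.fixed] = 0.0
            rn = np.linalg.norm(r)
            history.append(rn)
            if scale is None:
                scale = max(rn, 1e-12)
            if rn < tol * scale or rn < 1e-12:
                return u, p, rn, it
            kmat = sp.coo_matrix(
                (self._vals, (self._rows, self._cols)),
                shape=(self.ndof, self.ndof)).tocsr()
            kmat = _apply_dirichlet(kmat, self.fixed)
            try:
                du = spla.spsolve(kmat, -r)
            except Exception as exc:     # pragma: no cover
                raise SolverError(f"linear solve failed: {exc}")
            if not np.isfinite(du).all():
                raise SolverError("linear solve returned non-finite step")
            # damped update
            alpha = 1.0
            for _ in range(6):
                u_new = u + alpha * du[:self.nu]
                p_new = p + alpha * du[self.nu:]
                n_bad = self._residual_and_tangent(u_new, p_new,
                                                   gamma_vert)
                r_new = self._resid.copy()
                r_new[self.fixed] = 0.0
                if n_bad == 0 and np.linalg.norm(r_new) < rn * (1 + 1e-8):
                    break
                alpha *= 0.5
            else:
                raise SolverError(
                    "Newton line search failed; residual history: "
                    + ", ".join(f"{h:.3e}" for h in history))
            u, p = u_new, p_new
        raise SolverError(
            "Newton did not converge; residual history: "
            + ", ".join(f"{h:.3e}" for h in history))


def _apply_dirichlet(kmat: sp.csr_matrix, fixed: np.ndarray):
    fixed_idx = np.nonzero(fixed)[0]
    kmat = kmat.tolil()
    kmat[fixed_idx, :] = 0.0
    kmat[:, fixed_idx] = 0.0
    for i in fixed_idx:
        kmat[i, i] = 1.0
    return kmat.tocsr()


def basal_bcs(mesh: LvMesh, p2: P2Mesh) -> np.ndarray:
    """Fixed dofs: longitudinal (z) constraint on the whole basal plane,
    plus two in-plane pins to remove the remaining rigid modes."""
    zb = mesh.z_base
    on_base = np.abs(p2.points[:, 2] - zb) < 1e-6
    fixed = []
    for i in np.nonzero(on_base)[0]:
        fixed.append(3 * i + 2)
    base_vert = [i for i in np.nonzero(on_base)[0] if i < p2.n_vert]
    pin = base_vert[0]
    fixed += [3 * pin, 3 * pin + 1]
    # a second pin on the far side of the rim blocks rotation about z
    pin_pt = p2.points[pin]
    far = max(base_vert, key=lambda i: np.linalg.norm(
        p2.points[i][:2] - pin_pt[:2]))
    d = p2.points[far][:2] - pin_pt[:2]
    # constrain the component perpendicular to the separation direction
    fixed.append(3 * far + (1 if abs(d[0]) >= abs(d[1]) else 0))
    return np.unique(fixed)


# ---------------------------------------------------------------- fields
def stress_strain_magnitudes(state: MechState):
    """Per-element scalar stress/strain fields.

    Stress scalar: von Mises norm of the Cauchy stress; strain scalar:
    Frobenius norm of the elastic Green-Lagrange tensor E_e.  Both are
    evaluated at element centroids.
    """
    p2 = state.p2
    nel = len(p2.conn10)
    vm = np.empty(nel)
    em = np.empty(nel)
    lam_c = np.full(4, 0.25)
    dn = np.empty((10, 3))
    for e in range(nel):
        mk._p2_grads(lam_c, p2.dlams[e], dn)
        ue = state.u[p2.conn10[e]]
        gradu = ue.T @ dn
        fdef = np.eye(3) + gradu
        gf = state.gamma_vert[p2.vconn[e]].mean()
        gam = ActiveStrain(gf, state.kappa)
        f, s, n = state.triads[e]
        f0inv = (np.eye(3)
                 + (1 / (1 + gam.gamma_f) - 1) * np.outer(f, f)
                 + (1 / (1 + gam.gamma_s) - 1) * np.outer(s, s)
                 + (1 / (1 + gam.gamma_n) - 1) * np.outer(n, n))
        fe = fdef @ f0inv
        je = np.linalg.det(fe)
        pq = state.p[p2.vconn[e]].mean()
        feinv = np.linalg.inv(fe)
        dwdfe = state.mu * fe + (pq - state.mu) * feinv.T
        pk = dwdfe @ f0inv        # F0^-T = F0^-1 (symmetric)
        sigma = pk @ fdef.T / np.linalg.det(fdef)
        dev = sigma - np.trace(sigma) / 3.0 * np.eye(3)
        vm[e] = math.sqrt(1.5 * np.tensordot(dev, dev))
        ee = 0.5 * (fe.T @ fe - np.eye(3))
        em[e] = np.linalg.norm(ee)
    return vm, em


# ------------------------------------------------------------------ EM run
@dataclass
class EmFields:
    """Output of a staggered electromechanics run."""

    times: np.ndarray                  # mechanics sampling times (ms)
    volumes: np.ndarray                # cavity volumes (mL)
    ef: float                          # ejection fraction (%)
    edv: float
    esv: float
    activation: np.ndarray             # per-vertex activation time (ms)
    gamma_min: float
    snapshots: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _cell_gamma_tables(variant, cl, sl0, dt, n_beats, cell_types,
                       n_condition_min):
    """Unloaded single-cell SL traces per transmural cell type, turned
    into gamma_f(t) lookup tables over one steady-state beat."""
    from .coupled import pace
    from . import constants as c

    tables = {}
    for ct in cell_types:
        tr = pace(variant, ct, cl, n_beats=n_beats, record_last=1,
                  dt=dt, min_beats=n_condition_min)
        sl = tr["sl"]
        t = tr.t - tr.t[0]
        gamma = gamma_from_cell(sl, sl0)
        tables[ct] = (t, gamma)
    return tables


def run_em(preset: str = "NORMAL", variant: str = "HFPEF",
           t_end: float = 700.0, dt_mech: float = 10.0,
           material: Material = Material(), kappa: float = 4.0,
           n_theta: int = 12, n_long: int = 6, n_trans: int = 2,
           cl: float = 1000.0, cell_dt: float = 0.02,
           n_beats: int = 1000, n_condition_min: int = 200,
           sl0: float | None = None, cv_f: float = 65.0,
           snapshot_times: tuple = (), ep_mode: str = "eikonal",
           stimulate: bool = True, mesh: LvMesh | None = None,
           stim_radius: float = 14.0, newton_tol: float = 1e-8,
           gamma_tables: dict | None = None) -> EmFields:
    """Staggered electromechanics of one LV hypertrophy preset.

    Each mechanics step first advances the electrophysiology (per-vertex
    activation time plus the pre-paced unloaded cell model of the local
    cell type), projects the resulting fiber active strain gamma_f onto
    the mechanics mesh, then solves the finite-elasticity equilibrium.
    The electrical problem uses the calibrated anisotropic activation
    map (``ep_mode='eikonal'``); EF = (EDV - ESV)/EDV from the cavity
    volume extrema.  Without a stimulus the ventricle never activates,
    gamma stays 0 and EF = 0.
    """
    from .params import MmParams
    from .tissue import (assign_cell_types, default_stim_nodes,
                         activation_times_graph, ConductivitySet,
                         MonodomainProblem)
    from .remodeling import variant_spec

    mesh = mesh or lv_preset(preset, n_theta=n_theta, n_long=n_long,
                             n_trans=n_trans)
    fibers = rule_based_fibers(mesh)
    p2 = build_p2(mesh.points, mesh.tets)
    triads = element_triads(fibers, mesh.tets)
    solver = EquilibriumSolver(p2, triads, material, kappa,
                               basal_bcs(mesh, p2))
    labels = assign_cell_types(mesh.depth)
    spec = variant_spec(variant) if isinstance(variant, str) else variant

    sl0 = sl0 if sl0 is not None else MmParams().slset
    n_vert = mesh.n_nodes
    if stimulate:
        stim = default_stim_nodes(mesh, stim_radius)
        if ep_mode == "eikonal":
            act = activation_times_graph(
                mesh.points, mesh.tets, fibers, ConductivitySet(), cv_f,
                spec.conductivity_factor, np.nonzero(stim)[0])
        elif ep_mode == "monodomain":
            prob = MonodomainProblem(mesh.points, mesh.tets, mesh.depth,
                                     fibers, variant=spec)
            act = prob.run(min(t_end, 250.0), stim)
            act = np.where(np.isfinite(act), act, np.nanmax(act))
        else:
            raise ValueError(f"unknown ep_mode {ep_mode!r}")
        tables = gamma_tables if gamma_tables is not None else \
            _cell_gamma_tables(spec, cl, sl0, cell_dt, n_beats,
                               sorted(set(labels)), n_condition_min)
    else:
        act = np.full(n_vert, np.inf)
        tables = {}

    times = np.arange(0.0, t_end + 1e-9, dt_mech)
    volumes = np.empty(len(times))
    snapshots = {}
    u0 = None
    p0 = None
    gmin = 0.0
    for it, t in enumerate(times):
        gamma_vert = np.zeros(n_vert)
        for v in range(n_vert):
            tau = t - act[v]
            if tau >= 0.0 and labels[v] in tables:
                tt, gg = tables[labels[v]]
                gamma_vert[v] = np.interp(min(tau, tt[-1]), tt, gg)
        gmin = min(gmin, gamma_vert.min())
        if np.abs(gamma_vert).max() < 1e-12 and u0 is None:
            volumes[it] = cavity_volume(mesh)
            continue
        state = solver.solve(gamma_vert, u0=u0, p0=p0, tol=newton_tol)
        u0, p0 = state.u, state.p
        volumes[it] = cavity_volume(mesh, state.u_vert)
        for ts in snapshot_times:
            if abs(t - ts) < dt_mech / 2 and ts not in snapshots:
                vm, em = stress_strain_magnitudes(state)
                snapshots[ts] = {"stress": vm, "strain": em,
                                 "u": state.u_vert.copy()}
    edv = float(volumes.max())
    esv = float(volumes.min())
    ef = 100.0 * (edv - esv) / edv
    return EmFields(times, volumes, ef, edv, esv, act, gmin, snapshots,
                    meta={"preset": preset, "variant": getattr(
                        spec, "name", str(variant)),
                        "thickness": mesh.thickness,
                        "n_tets": len(mesh.tets), "dt_mech": dt_mech,
                        "ep_mode": ep_mode})
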