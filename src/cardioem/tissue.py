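"""Monodomain tissue electrophysiology.

The membrane potential obeys  Cm dV/dt = -(I_ion + I_stim) + div(D grad V)
with the anisotropic tensor  D = sigma_f f x f + sigma_s s x s +
sigma_n n x n.  The printed conductivities (3.0 / 0.1 / 0.31525) are
treated as relative anisotropy weights: the mapping from sigma to an
effective diffusivity (mm^2/ms) is a single calibration constant chosen
so a planar wave in a control-tissue strand travels at 65 cm/s in the
fiber direction.  Time stepping is Strang-split: half-step reaction
(cell kernels), Crank-Nicolson diffusion, half-step reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constants as c
from . import _kernels as k
from .params import MmParams, CELL_TYPES, ENDO, EPI, MCELL
from .remodeling import build_variant
from .state import initial_y
from .tables import build_table

# Effective fiber-direction diffusivity per unit conductivity weight
# (mm^2/ms); calibrated once against the 65 cm/s planar-wave target on a
# 20 mm strand at dx = 0.1 mm (see measure_cv / scripts).
DIFFUSIVITY_PER_SIGMA = 0.1000

_TYPE_CODE = {ENDO: 0, EPI: 1, MCELL: 2}
_TYPE_ORDER = (ENDO, EPI, MCELL)


class GeometryError(ValueError):
    pass


class BlockError(RuntimeError):
    """Propagation failure: the far end of the domain never activated."""


@dataclass
class ConductivitySet:
    """Anisotropic conductivity weights and membrane capacitance."""

    sigma_f: float = 3.0
    sigma_s: float = 0.1
    sigma_n: float = 0.31525
    cm: float = 1.0

    def scaled(self, factor: float) -> "ConductivitySet":
        return ConductivitySet(self.sigma_f * factor,
                               self.sigma_s * factor,
                               self.sigma_n * factor, self.cm)


@dataclass
class TransmuralLayout:
    """Partition of normalised transmural depth into cell-type bands
    (endocardium at depth 0)."""

    bands: tuple = ((0.0, 0.6, ENDO), (0.6, 0.9, MCELL), (0.9, 1.0, EPI))

    def __post_init__(self):
        lo = 0.0
        for a, b, ct in self.bands:
            if abs(a - lo) > 1e-12 or b <= a or ct not in CELL_TYPES:
                raise GeometryError("layout bands must tile [0, 1]")
            lo = b
        if abs(lo - 1.0) > 1e-12:
            raise GeometryError("layout bands must tile [0, 1]")

    def cell_type(self, depth: float) -> str:
        for a, b, ct in self.bands:
            if depth < b or b == self.bands[-1][1]:
                return ct
        return self.bands[-1][2]


def assign_cell_types(depth: np.ndarray,
                      layout: TransmuralLayout | None = None) -> np.ndarray:
    """Per-node cell-type labels from normalised transmural depth."""
    depth = np.asarray(depth, float)
    if (depth < -1e-9).any() or (depth > 1 + 1e-9).any():
        raise GeometryError("transmural depth outside [0, 1]")
    layout = layout or TransmuralLayout()
    out = np.empty(len(depth), dtype=object)
    for a, b, ct in layout.bands:
        mask = (depth >= a - 1e-12) & (depth < b)
        out[mask] = ct
    out[depth >= layout.bands[-1][1] - 1e-12] = layout.bands[-1][2]
    return out


def diffusion_tensor(f: np.ndarray, s: np.ndarray, n: np.ndarray,
                     cond: ConductivitySet) -> np.ndarray:
    """Anisotropic tensor sigma_f f x f + sigma_s s x s + sigma_n n x n.

    Requires an orthonormal triad; symmetric PSD with eigenvalues equal
    to the three conductivities.
    """
    f, s, n = (np.asarray(v, float) for v in (f, s, n))
    for a, b in ((f, s), (f, n), (s, n)):
        if abs(np.dot(a, b)) > 1e-6:
            raise GeometryError("fiber triad is not orthogonal")
    for a in (f, s, n):
        if abs(np.dot(a, a) - 1.0) > 1e-6:
            raise GeometryError("fiber triad is not normalised")
    return (cond.sigma_f * np.outer(f, f) + cond.sigma_s * np.outer(s, s)
            + cond.sigma_n * np.outer(n, n))


def _prm_tabs(variant, dt: float):
    """Kernel parameter arrays and rate tables for all three cell types
    under ``variant`` (name or VariantSpec)."""
    from .remodeling import variant_spec, VariantSpec
    from .params import pack_params

    if isinstance(variant, str):
        spec = variant_spec(variant)
    elif isinstance(variant, VariantSpec):
        spec = variant
    else:
        raise ValueError(f"cannot interpret variant {variant!r}")
    prms = np.zeros((3, c.NP_PARAMS))
    tabs = np.zeros((3, c.N_V, c.N_TCOLS))
    from .remodeling import apply_variant
    from .params import EpParams

    for ct in _TYPE_ORDER:
        ep = EpParams().for_cell_type(ct)
        ep, mm = apply_variant(spec, ep, MmParams())
        code = _TYPE_CODE[ct]
        prms[code] = pack_params(ep, mm)
        tabs[code] = build_table(ep, dt)
    return spec, prms, tabs


# ------------------------------------------------------------- 1D strand
@dataclass
class StrandResult:
    x: np.ndarray                 # node positions (mm)
    activation: np.ndarray        # per-node activation time (ms)
    cv: float                     # conduction velocity (cm/s)


def _strand_operators(n: int, d_eff: float, dx: float, dt: float):
    """Crank-Nicolson factorisation for the 1D Laplacian with no-flux
    boundaries."""
    main = np.full(n, -2.0)
    main[0] = main[-1] = -1.0
    lap = sp.diags([np.ones(n - 1), main, np.ones(n - 1)], [-1, 0, 1],
                   format="csc") * (d_eff / dx ** 2)
    ident = sp.identity(n, format="csc")
    lhs = spla.splu((ident - 0.5 * dt * lap).tocsc())
    rhs = (ident + 0.5 * dt * lap).tocsr()
    return lhs, rhs


def run_strand(length_mm: float = 20.0, dx: float = 0.2,
               cond: ConductivitySet | None = None,
               variant="CONTROL", cell_type: str = ENDO,
               dt: float = 0.02, t_max: float = 80.0,
               stim_frac: float = 0.05, scheme: int = 2,
               conductivity_factor: float | None = None,
               record_v_at: float | None = None) -> StrandResult:
    """Planar-wave propagation along a fiber-direction strand.

    Stimulates the first ``stim_frac`` of the strand and records each
    node's activation time (instant of maximum dV/dt).  ``scheme`` 2
    uses the symmetrised second-order reaction step.
    """
    cond = cond or ConductivitySet()
    spec, prms, tabs = _prm_tabs(variant, dt / 2 if scheme == 1 else dt / 4)
    factor = (spec.conductivity_factor if conductivity_factor is None
              else conductivity_factor)
    sigma = cond.sigma_f * factor
    if sigma <= 0:
        raise BlockError("zero fiber conductivity: no propagation")
    d_eff = DIFFUSIVITY_PER_SIGMA * sigma / cond.cm

    n = int(round(length_mm / dx)) + 1
    x = np.linspace(0.0, length_mm, n)
    types = np.full(n, _TYPE_CODE[cell_type], dtype=np.int64)
    ystates = np.tile(initial_y(cell_type), (n, 1))
    lhs, rhs = _strand_operators(n, d_eff, dx, dt)

    istim = np.zeros(n)
    stim_nodes = x <= stim_frac * length_mm
    n_steps = int(round(t_max / dt))
    act = np.full(n, np.nan)
    best_dv = np.full(n, 2.0)     # require an upstroke > 2 mV/ms
    v_prev = ystates[:, c.Y_V].copy()
    v_record = None
    react = k.react_nodes if scheme == 1 else k.react_nodes2
    half = dt / 2.0
    for step_i in range(n_steps):
        t = step_i * dt
        istim[:] = 0.0
        if t < 1.0:
            istim[stim_nodes] = -80.0
        react(ystates, prms, tabs, types, half, 1, istim)
        v = ystates[:, c.Y_V]
        v[:] = lhs.solve(rhs @ v)
        react(ystates, prms, tabs, types, half, 1, istim)
        dv = (ystates[:, c.Y_V] - v_prev) / dt
        upd = dv > best_dv
        best_dv[upd] = dv[upd]
        act[upd] = t + dt
        v_prev[:] = ystates[:, c.Y_V]
        if record_v_at is not None and abs(t + dt - record_v_at) < dt / 2:
            v_record = ystates[:, c.Y_V].copy()
    tail = x > 0.9 * length_mm
    if np.isnan(act[tail]).any():
        raise BlockError("far end of the strand never activated")
    # linear fit over the central window (exclude 25% at each end)
    core_w = (x >= 0.25 * length_mm) & (x <= 0.75 * length_mm)
    slope = np.polyfit(x[core_w], act[core_w], 1)[0]   # ms/mm
    cv = 100.0 / slope                                  # cm/s
    res = StrandResult(x, act, float(cv))
    if record_v_at is not None:
        res.v_snapshot = v_record
    return res


def measure_cv(strand_length: float = 20.0, dx: float = 0.2,
               cond: ConductivitySet | None = None,
               variant="CONTROL", **kwargs) -> float:
    """Fiber-direction conduction velocity (cm/s) from a strand run."""
    if strand_length < 20.0:
        raise GeometryError("strand must be at least 20 mm")
    return run_strand(strand_length, dx, cond, variant, **kwargs).cv


# --------------------------------------------------------- mesh problem
class MonodomainProblem:
    """Reaction-diffusion on a tetrahedral mesh (P1 elements, lumped
    mass, implicit Crank-Nicolson diffusion, Strang splitting)."""

    def __init__(self, points, tets, depth, fibers,
                 cond: ConductivitySet | None = None, variant="CONTROL",
                 layout: TransmuralLayout | None = None,
                 dt: float = 0.02, dt_diffusion: float = 0.1,
                 scheme: int = 1):
        self.points = np.asarray(points, float)
        self.tets = np.asarray(tets)
        self.cond = cond or ConductivitySet()
        self.dt = dt
        self.dt_diffusion = dt_diffusion
        self.scheme = scheme
        if abs(dt_diffusion / dt - round(dt_diffusion / dt)) > 1e-9:
            raise ValueError("dt_diffusion must be a multiple of dt")
        # reaction substeps per Strang half, chosen so the substep
        # never exceeds the requested dt
        import math as _math

        self.n_sub = max(1, _math.ceil(dt_diffusion / (2.0 * dt) - 1e-12))
        self.dt_react = dt_diffusion / (2.0 * self.n_sub)
        table_dt = self.dt_react if scheme == 1 else self.dt_react / 2
        self.spec, self.prms, self.tabs = _prm_tabs(variant, table_dt)
        labels = assign_cell_types(depth, layout)
        self.labels = labels
        self.types = np.array([_TYPE_CODE[ct] for ct in labels],
                              dtype=np.int64)
        self.ystates = np.vstack([initial_y(ct) for ct in labels])
        self._assemble(fibers)

    def _assemble(self, fibers):
        pts, tets = self.points, self.tets
        n = len(pts)
        factor = self.spec.conductivity_factor
        kcal = DIFFUSIVITY_PER_SIGMA / self.cond.cm
        rows, cols, vals = [], [], []
        lumped = np.zeros(n)
        for tet in tets:
            x = pts[tet]
            mat = np.hstack([np.ones((4, 1)), x])
            vol = abs(np.linalg.det(mat)) / 6.0
            grads = np.linalg.inv(mat)[1:, :].T        # (4, 3)
            dten = np.zeros((3, 3))
            for vtx in tet:
                dten += diffusion_tensor(fibers.f[vtx], fibers.s[vtx],
                                         fibers.n[vtx], self.cond)
            dten *= kcal * factor / 4.0
            ke = vol * grads @ dten @ grads.T
            for a in range(4):
                lumped[tet[a]] += vol / 4.0
                for b in range(4):
                    rows.append(tet[a])
                    cols.append(tet[b])
                    vals.append(ke[a, b])
        kmat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        minv = sp.diags(1.0 / lumped)
        dtd = self.dt_diffusion
        ident = sp.identity(n, format="csc")
        self._lhs = spla.splu((ident + 0.5 * dtd * minv @ kmat).tocsc())
        self._rhs = (ident - 0.5 * dtd * minv @ kmat).tocsr()

    def run(self, t_end: float, stim_nodes: np.ndarray,
            stim_amp: float = -80.0, stim_dur: float = 1.0,
            on_step=None):
        """Integrate to ``t_end`` ms; returns per-node activation times
        (max-dV/dt instant).  ``on_step(t, V)`` is called after every
        diffusion step when given."""
        n = len(self.points)
        istim = np.zeros(n)
        act = np.full(n, np.nan)
        best_dv = np.full(n, 2.0)
        v_prev = self.ystates[:, c.Y_V].copy()
        react = k.react_nodes if self.scheme == 1 else k.react_nodes2
        dtd = self.dt_diffusion
        n_steps = int(round(t_end / dtd))
        for si in range(n_steps):
            t = si * dtd
            istim[:] = 0.0
            if t < stim_dur:
                istim[stim_nodes] = stim_amp
            react(self.ystates, self.prms, self.tabs, self.types,
                  self.dt_react, self.n_sub, istim)
            v = self.ystates[:, c.Y_V]
            v[:] = self._lhs.solve(self._rhs @ v)
            react(self.ystates, self.prms, self.tabs, self.types,
                  self.dt_react, self.n_sub, istim)
            if not np.isfinite(v).all():
                bad = int(np.nonzero(~np.isfinite(v))[0][0])
                raise RuntimeError(
                    f"monodomain integration diverged at node {bad}, "
                    f"t={t + dtd} ms")
            dv = (v - v_prev) / dtd
            upd = dv > best_dv
            best_dv[upd] = dv[upd]
            act[upd] = t + dtd
            v_prev[:] = v
            if on_step is not None:
                on_step(t + dtd, v)
        return act


def default_stim_nodes(mesh, radius_mm: float = 6.0) -> np.ndarray:
    """Three early-activation endocardial patches (apical septal, mid
    free wall, basal), the default in lieu of patient-derived sites."""
    pts = mesh.points
    endo = mesh.depth < 1e-9
    r = mesh.r_endo
    zb, za = mesh.z_base, -mesh.a_endo
    seeds = np.array([
        [0.6 * r, 0.0, za + 0.25 * (zb - za)],
        [-0.9 * r, 0.0, za + 0.55 * (zb - za)],
        [0.0, 0.9 * r, za + 0.9 * (zb - za)],
    ])
    mask = np.zeros(len(pts), bool)
    for sd in seeds:
        dist = np.linalg.norm(pts - sd, axis=1)
        mask |= endo & (dist < radius_mm)
    if not mask.any():
        raise GeometryError("no endocardial nodes near stimulus seeds")
    return mask


# ------------------------------------------------- eikonal activation
def activation_times_graph(points, tets, fibers,
                           cond: ConductivitySet | None = None,
                           cv_f: float = 65.0,
                           conductivity_factor: float = 1.0,
                           source_nodes=None) -> np.ndarray:
    """Fast anisotropic activation map: shortest travel time on the
    mesh edge graph with direction-dependent speed  cv(d) = cv_f *
    sqrt(d.T S d / sigma_f),  S the conductivity tensor.  Used by the
    staggered electromechanics loop as an inexpensive stand-in for a
    full monodomain solve on coarse meshes."""
    from scipy.sparse.csgraph import dijkstra

    cond = cond or ConductivitySet()
    points = np.asarray(points, float)
    cv_f = cv_f * np.sqrt(conductivity_factor)
    edges = set()
    for tet in np.asarray(tets):
        for a in range(4):
            for b in range(a + 1, 4):
                edges.add((min(tet[a], tet[b]), max(tet[a], tet[b])))
    rows, cols, w = [], [], []
    for a, b in edges:
        d = points[b] - points[a]
        ln = np.linalg.norm(d)
        dhat = d / ln
        mid_f = fibers.f[a] + fibers.f[b]
        mid_s = fibers.s[a] + fibers.s[b]
        mid_n = fibers.n[a] + fibers.n[b]
        sig = (cond.sigma_f * np.dot(dhat, mid_f / 2) ** 2
               + cond.sigma_s * np.dot(dhat, mid_s / 2) ** 2
               + cond.sigma_n * np.dot(dhat, mid_n / 2) ** 2)
        speed = cv_f / 100.0 * np.sqrt(max(sig, 1e-6) / cond.sigma_f)
        rows.append(a)
        cols.append(b)
        w.append(ln / speed)            # ms
    n = len(points)
    g = sp.coo_matrix((w, (rows, cols)), shape=(n, n))
    g = g + g.T
    if source_nodes is None:
        raise ValueError("source_nodes required")
    times = dijkstra(g.tocsr(), directed=False, indices=source_nodes)
    return times.min(axis=0)
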