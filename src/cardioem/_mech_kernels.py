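"""Numba kernels for the mixed P2-P1 finite-elasticity solver.

Displacements are discretised with quadratic (10-node) tetrahedra,
pressure with linear (4-node) tetrahedra.  The stored energy is the
mixed compressible neo-Hookean form

    W = mu/2 (I : Ce - 3) - mu ln Je + p ln Je - p^2 / (2 lambda)

evaluated on the elastic part Fe = F F0^-1 of the active-strain
decomposition; det F0 = 1 by construction, so the reference volume
measure is unchanged.  Element residuals are analytic; consistent
tangents are assembled by forward differences on the element residual.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# degree-3 quadrature on the reference tetrahedron (barycentric)
_QP = np.array([
    [0.25, 0.25, 0.25, 0.25],
    [0.5, 1.0 / 6.0, 1.0 / 6.0, 1.0 / 6.0],
    [1.0 / 6.0, 0.5, 1.0 / 6.0, 1.0 / 6.0],
    [1.0 / 6.0, 1.0 / 6.0, 0.5, 1.0 / 6.0],
    [1.0 / 6.0, 1.0 / 6.0, 1.0 / 6.0, 0.5],
])
_QW = np.array([-0.8, 0.45, 0.45, 0.45, 0.45])

# local edge ordering of the 10-node tetrahedron
EDGE_LOCAL = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


@njit(cache=True, fastmath=True)
def _p2_grads(lam, dlam, out):
    """Gradients of the 10 quadratic shape functions at barycentric
    point ``lam``; ``dlam`` is the constant (4,3) barycentric gradient."""
    for v in range(4):
        for j in range(3):
            out[v, j] = (4.0 * lam[v] - 1.0) * dlam[v, j]
    for e in range(6):
        a, b = EDGE_LOCAL[e, 0], EDGE_LOCAL[e, 1]
        for j in range(3):
            out[4 + e, j] = 4.0 * (lam[a] * dlam[b, j]
                                   + lam[b] * dlam[a, j])


@njit(cache=True, fastmath=True)
def _inv3(a, out):
    d = (a[0, 0] * (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
         - a[0, 1] * (a[1, 0] * a[2, 2] - a[1, 2] * a[2, 0])
         + a[0, 2] * (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0]))
    out[0, 0] = (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1]) / d
    out[0, 1] = (a[0, 2] * a[2, 1] - a[0, 1] * a[2, 2]) / d
    out[0, 2] = (a[0, 1] * a[1, 2] - a[0, 2] * a[1, 1]) / d
    out[1, 0] = (a[1, 2] * a[2, 0] - a[1, 0] * a[2, 2]) / d
    out[1, 1] = (a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]) / d
    out[1, 2] = (a[0, 2] * a[1, 0] - a[0, 0] * a[1, 2]) / d
    out[2, 0] = (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0]) / d
    out[2, 1] = (a[0, 1] * a[2, 0] - a[0, 0] * a[2, 1]) / d
    out[2, 2] = (a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]) / d
    return d


@njit(cache=True, fastmath=True)
def elem_residual(dlam, vol, ue, pe, gv, fvec, svec, nvec, kappa,
                  mu, lam_pen, r):
    """Element residual (30 displacement + 4 pressure entries).

    ``gv`` holds the vertex fiber active strains gamma_f; the
    cross-fiber strains follow gamma_n = K gamma_f and gamma_s =
    1/((1+gamma_f)(1+gamma_n)) - 1, so det F0 = 1 identically.
    Returns 1.0 if any quadrature point inverted (det Fe <= 0).
    """
    r[:] = 0.0
    dn = np.empty((10, 3))
    gradu = np.empty((3, 3))
    f0inv = np.empty((3, 3))
    fdef = np.empty((3, 3))
    fe = np.empty((3, 3))
    feinv = np.empty((3, 3))
    pk = np.empty((3, 3))
    bad = 0.0
    for q in range(_QP.shape[0]):
        lamq = _QP[q]
        w = _QW[q] * vol
        _p2_grads(lamq, dlam, dn)
        # displacement gradient
        for i in range(3):
            for j in range(3):
                acc = 0.0
                for a in range(10):
                    acc += ue[a, i] * dn[a, j]
                gradu[i, j] = acc
        # active strain at the quadrature point (P1 interpolation)
        gf = (lamq[0] * gv[0] + lamq[1] * gv[1] + lamq[2] * gv[2]
              + lamq[3] * gv[3])
        gn = kappa * gf
        gs = 1.0 / ((1.0 + gf) * (1.0 + gn)) - 1.0
        af = 1.0 / (1.0 + gf) - 1.0
        a_s = 1.0 / (1.0 + gs) - 1.0
        an = 1.0 / (1.0 + gn) - 1.0
        for i in range(3):
            for j in range(3):
                f0inv[i, j] = (af * fvec[i] * fvec[j]
                               + a_s * svec[i] * svec[j]
                               + an * nvec[i] * nvec[j])
            f0inv[i, i] += 1.0
        # F, Fe, Je
        for i in range(3):
            for j in range(3):
                fdef[i, j] = gradu[i, j]
            fdef[i, i] += 1.0
        for i in range(3):
            for j in range(3):
                acc = 0.0
                for m in range(3):
                    acc += fdef[i, m] * f0inv[m, j]
                fe[i, j] = acc
        je = _inv3(fe, feinv)
        if je <= 1e-10:
            bad = 1.0
            return bad
        pq = (lamq[0] * pe[0] + lamq[1] * pe[1] + lamq[2] * pe[2]
              + lamq[3] * pe[3])
        # first Piola stress: (mu Fe + (p - mu) Fe^-T) F0^-T
        for i in range(3):
            for j in range(3):
                acc = 0.0
                for m in range(3):
                    acc += (mu * fe[i, m]
                            + (pq - mu) * feinv[m, i]) * f0inv[j, m]
                pk[i, j] = acc
        for a in range(10):
            for i in range(3):
                r[3 * a + i] += w * (pk[i, 0] * dn[a, 0]
                                     + pk[i, 1] * dn[a, 1]
                                     + pk[i, 2] * dn[a, 2])
        lnj = np.log(je)
        for b in range(4):
            r[30 + b] += w * lamq[b] * (lnj - pq / lam_pen)
    return bad


@njit(cache=True, fastmath=True)
def assemble(conn10, vconn, dlams, vols, triads, kappa, u_flat, p_vec,
             gamma_vert, mu, lam_pen, rows, cols, vals, resid):
    """Assemble the global residual and the forward-difference tangent.

    ``rows/cols/vals`` must hold nel*34*34 entries; ``resid`` is the
    global residual (3*n_p2 + n_vert).  Returns the number of inverted
    quadrature evaluations encountered (0 for a clean assembly).
    """
    nel = conn10.shape[0]
    nu = u_flat.shape[0]
    ue = np.empty((10, 3))
    pe = np.empty(4)
    gv = np.empty(4)
    r0 = np.empty(34)
    r1 = np.empty(34)
    dofs = np.empty(34, dtype=np.int64)
    n_bad = 0
    resid[:] = 0.0
    for e in range(nel):
        for a in range(10):
            node = conn10[e, a]
            for i in range(3):
                ue[a, i] = u_flat[3 * node + i]
            for i in range(3):
                dofs[3 * a + i] = 3 * node + i
        for b in range(4):
            vb = vconn[e, b]
            pe[b] = p_vec[vb]
            gv[b] = gamma_vert[vb]
            dofs[30 + b] = nu + vb
        fvec = triads[e, 0]
        svec = triads[e, 1]
        nvec = triads[e, 2]
        bad = elem_residual(dlams[e], vols[e], ue, pe, gv, fvec, svec,
                            nvec, kappa, mu, lam_pen, r0)
        if bad > 0.0:
            n_bad += 1
            continue
        for i in range(34):
            resid[dofs[i]] += r0[i]
        # forward-difference tangent, column by column
        base = e * 34 * 34
        for jcol in range(34):
            if jcol < 30:
                a = jcol // 3
                i = jcol % 3
                h = 1e-7
                ue[a, i] += h
                elem_residual(dlams[e], vols[e], ue, pe, gv, fvec, svec,
                              nvec, kappa, mu, lam_pen, r1)
                ue[a, i] -= h
            else:
                b = jcol - 30
                h = 1e-7 * max(1.0, abs(pe[b]))
                pe[b] += h
                elem_residual(dlams[e], vols[e], ue, pe, gv, fvec, svec,
                              nvec, kappa, mu, lam_pen, r1)
                pe[b] -= h
            for irow in range(34):
                idx = base + jcol * 34 + irow
                rows[idx] = dofs[irow]
                cols[idx] = dofs[jcol]
                vals[idx] = (r1[irow] - r0[irow]) / h
    return n_bad
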