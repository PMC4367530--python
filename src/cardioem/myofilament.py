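"""Myofilament (crossbridge cycling) layer.

Active force comes from a four-state regulatory-unit / crossbridge cycle
with mean-distortion dynamics; passive force from exponential titin and
collagen elements.  The troponin binding flux J_Trop (uM/ms) produced
here is the myofilament's contribution to the cytosolic Ca2+ balance of
the coupled cell.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from . import constants as c
from . import _kernels as k
from .params import EpParams, MmParams, pack_params
from .state import initial_y

ISOMETRIC = "isometric"
UNLOADED = "unloaded"


class DomainError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


_MM_FIELDS = [
    ("n", c.Y_N), ("xbprer", c.Y_XBPRER), ("xbpostr", c.Y_XBPOSTR),
    ("xxbprer", c.Y_XXBPRER), ("xxbpostr", c.Y_XXBPOSTR),
    ("trpncal", c.Y_TRPNL), ("trpncah", c.Y_TRPNH),
    ("n_noxb", c.Y_NNOXB), ("sl", c.Y_SL), ("vsl", c.Y_VSL),
]


@dataclass
class MmState:
    """Crossbridge occupancies (N non-permissive, P permissive implied
    as 1 - N - XBprer - XBpostr), mean distortions (um), troponin site
    occupancies, sarcomere length (um) and its velocity."""

    n: float = 0.99
    xbprer: float = 1e-4
    xbpostr: float = 1e-5
    xxbprer: float = 0.0
    xxbpostr: float = 0.007
    trpncal: float = 0.0147
    trpncah: float = 0.13
    n_noxb: float = 0.99
    sl: float = 1.9
    vsl: float = 0.0

    @property
    def p(self) -> float:
        """Permissive non-crossbridge fraction (algebraic closure)."""
        return 1.0 - self.n - self.xbprer - self.xbpostr

    @classmethod
    def from_array(cls, y: np.ndarray) -> "MmState":
        return cls(**{nm: float(y[i]) for nm, i in _MM_FIELDS})

    def to_array(self, y: np.ndarray | None = None) -> np.ndarray:
        if y is None:
            y = initial_y()
        for nm, i in _MM_FIELDS:
            y[i] = getattr(self, nm)
        return y


def _prm(params: MmParams) -> np.ndarray:
    return pack_params(EpParams(), params)


def mm_rates(state: MmState, cai: float, params: MmParams,
             mode: str = ISOMETRIC):
    """Myofilament state derivatives at cytosolic Ca ``cai`` (mM).

    Returns (rates dict, J_Trop in uM/ms, active force, passive force);
    in isometric mode dSL/dt = 0, in unloaded mode the sarcomere length
    follows the force-balance dynamics.
    """
    if cai <= 0:
        raise DomainError("cai must be > 0 (mM)")
    if mode not in (ISOMETRIC, UNLOADED):
        raise DomainError(f"unknown mode {mode!r}")
    y = state.to_array()
    # the permissive fraction is the algebraic closure, so "total
    # drift" shows up as an occupancy leaving [0, 1]
    if (state.p < -1e-3 or min(state.n, state.xbprer,
                               state.xbpostr) < -1e-3
            or max(state.n, state.xbprer, state.xbpostr) > 1.0 + 1e-3):
        raise ConvergenceError(
            "crossbridge occupancies outside [0, 1]: total drifted")
    out = k._rice(y, _prm(params), 1000.0 * cai,
                  1 if mode == ISOMETRIC else 0)
    (dn, dxbprer, dxbpostr, dxprer, dxpostr, dtrpnl, dtrpnh, dnnoxb,
     dsl, dvsl, jtrop, f_act, f_pas) = out
    rates = {"n": dn, "xbprer": dxbprer, "xbpostr": dxbpostr,
             "xxbprer": dxprer, "xxbpostr": dxpostr, "trpncal": dtrpnl,
             "trpncah": dtrpnh, "n_noxb": dnnoxb, "sl": dsl, "vsl": dvsl}
    return rates, float(jtrop), float(f_act), float(f_pas)


@dataclass
class PassiveForce:
    """Titin + collagen passive force decomposition (normalised)."""

    titin: float
    collagen: float

    @property
    def total(self) -> float:
        return self.titin + self.collagen

    def __float__(self) -> float:
        return self.total


def passive_force(sl: float, params: MmParams) -> PassiveForce:
    """Passive (titin + collagen) force at sarcomere length ``sl`` (um).

    The titin component vanishes at the resting length and grows
    monotonically (and linearly in PCon_titin) above it; the collagen
    component engages only above its engagement length.
    """
    if not params.slmin <= sl <= params.slmax:
        raise DomainError(
            f"sarcomere length {sl} outside [{params.slmin}, "
            f"{params.slmax}] um")
    ds = sl - params.slrest
    titin = float(np.sign(ds) * params.pcont
                  * (np.exp(params.pexpt * abs(ds)) - 1.0))
    if sl > params.slc:
        coll = float(params.pconc
                     * (np.exp(params.pexpc * (sl - params.slc)) - 1.0))
    else:
        coll = 0.0
    return PassiveForce(titin, coll)


@dataclass
class FpCaPoint:
    pca: float
    total: float
    passive: float

    @property
    def active(self) -> float:
        return self.total - self.passive


def steady_fpca(pca_grid, sl: float, params: MmParams,
                dt: float = 0.01, t_max: float = 20000.0,
                rel_tol: float = 1e-6) -> list[FpCaPoint]:
    """Steady-state force-pCa relation at fixed sarcomere length.

    Each grid point is integrated at clamped Ca until the active force
    is stationary (relative change < ``rel_tol`` per ms).  Returns a
    list of (pCa, total force, passive force) points.
    """
    pca_grid = list(pca_grid)
    if any(not 4.0 <= p <= 8.0 for p in pca_grid):
        raise DomainError("pCa grid must lie within [4, 8]")
    prm = _prm(params)
    out = []
    for pca in pca_grid:
        cai_um = 10.0 ** (6.0 - pca)
        y = MmState(sl=sl).to_array()
        y[c.Y_SL] = sl
        f_act, f_pas, ok = k.mm_relax_clamped(y, prm, cai_um, dt, t_max,
                                              1, rel_tol)
        if not ok:
            raise ConvergenceError(
                f"F-pCa point pCa={pca} did not converge within "
                f"{t_max} ms")
        out.append(FpCaPoint(pca, f_act + f_pas, f_pas))
    return out
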