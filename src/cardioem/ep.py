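"""Electrophysiology layer: state container, rate evaluation, currents.

The cytosolic Ca2+ rate is owned by the coupled-cell balance (see
:mod:`cardioem.coupled`) and is therefore not returned by
:func:`ep_rates`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from . import constants as c
from . import _kernels as k
from .params import EpParams, MmParams, pack_params, CELL_TYPES
from .state import initial_y
from .tables import build_table


class InvalidStateError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


_EP_FIELDS = [
    ("v", c.Y_V), ("nai", c.Y_NAI), ("nass", c.Y_NASS), ("ki", c.Y_KI),
    ("kss", c.Y_KSS), ("cai", c.Y_CAI), ("cass", c.Y_CASS),
    ("cansr", c.Y_CANSR), ("cajsr", c.Y_CAJSR),
    ("m", c.Y_M), ("hf", c.Y_HF), ("hs", c.Y_HS), ("j", c.Y_J),
    ("hsp", c.Y_HSP), ("jp", c.Y_JP), ("ml", c.Y_ML), ("hl", c.Y_HL),
    ("hlp", c.Y_HLP), ("a", c.Y_A), ("i_f", c.Y_IF), ("i_s", c.Y_IS),
    ("ap", c.Y_AP), ("ifp", c.Y_IFP), ("isp", c.Y_ISP),
    ("d", c.Y_D), ("ff", c.Y_FF), ("fs", c.Y_FS), ("fcaf", c.Y_FCAF),
    ("fcas", c.Y_FCAS), ("jca", c.Y_JCA), ("ffp", c.Y_FFP),
    ("fcafp", c.Y_FCAFP), ("nca", c.Y_NCA), ("xrf", c.Y_XRF),
    ("xrs", c.Y_XRS), ("xs1", c.Y_XS1), ("xs2", c.Y_XS2),
    ("xk1", c.Y_XK1), ("jrelnp", c.Y_JRELNP), ("jrelp", c.Y_JRELP),
    ("camkt", c.Y_CAMKT),
]

_GATE_NAMES = {n for n, i in _EP_FIELDS
               if i in c.RL_GATES or i == c.Y_NCA}
_CONC_NAMES = {"nai", "nass", "ki", "kss", "cai", "cass", "cansr",
               "cajsr"}


@dataclass
class EpState:
    """Named view of the electrophysiology entries of the state vector."""

    v: float
    nai: float
    nass: float
    ki: float
    kss: float
    cai: float
    cass: float
    cansr: float
    cajsr: float
    m: float
    hf: float
    hs: float
    j: float
    hsp: float
    jp: float
    ml: float
    hl: float
    hlp: float
    a: float
    i_f: float
    i_s: float
    ap: float
    ifp: float
    isp: float
    d: float
    ff: float
    fs: float
    fcaf: float
    fcas: float
    jca: float
    ffp: float
    fcafp: float
    nca: float
    xrf: float
    xrs: float
    xs1: float
    xs2: float
    xk1: float
    jrelnp: float
    jrelp: float
    camkt: float

    @classmethod
    def from_array(cls, y: np.ndarray) -> "EpState":
        return cls(**{n: float(y[i]) for n, i in _EP_FIELDS})

    def to_array(self, y: np.ndarray | None = None) -> np.ndarray:
        if y is None:
            y = initial_y()
        for n, i in _EP_FIELDS:
            y[i] = getattr(self, n)
        return y

    def validate(self) -> None:
        for f in dc_fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val):
                raise InvalidStateError(
                    f"state entry {f.name!r} is not finite: {val}")
        for n in sorted(_GATE_NAMES):
            val = getattr(self, n)
            if not 0.0 <= val <= 1.0:
                raise InvalidStateError(
                    f"gating variable {n!r} outside [0, 1]: {val}")
        for n in sorted(_CONC_NAMES):
            if getattr(self, n) <= 0:
                raise InvalidStateError(
                    f"concentration {n!r} must be > 0")


@dataclass
class CurrentSet:
    """Instantaneous transmembrane currents (uA/uF) and SR fluxes
    (mM/ms)."""

    ina: float
    inal: float
    ito: float
    ical: float
    ikr: float
    iks: float
    ik1: float
    inaca_i: float
    inaca_ss: float
    inak: float
    inab: float
    icab: float
    ipca: float
    jup: float
    jleak: float
    jrel: float
    jdiff: float

    @classmethod
    def from_kernel(cls, cur: np.ndarray) -> "CurrentSet":
        gx = c.CUR_INDEX
        return cls(
            ina=cur[gx["ina"]], inal=cur[gx["inal"]], ito=cur[gx["ito"]],
            ical=cur[gx["ical"]], ikr=cur[gx["ikr"]], iks=cur[gx["iks"]],
            ik1=cur[gx["ik1"]], inaca_i=cur[gx["inaca_i"]],
            inaca_ss=cur[gx["inaca_ss"]], inak=cur[gx["inak"]],
            inab=cur[gx["inab"]], icab=cur[gx["icab"]],
            ipca=cur[gx["ipca"]], jup=cur[gx["jup"]],
            jleak=cur[gx["jleak"]], jrel=cur[gx["jrel"]],
            jdiff=cur[gx["jdiff"]])


def initial_state(cell_type: str) -> EpState:
    """Published resting initial conditions for ``cell_type``."""
    if cell_type not in CELL_TYPES:
        raise ConfigurationError(
            f"unknown cell type {cell_type!r}; valid: {CELL_TYPES}")
    return EpState.from_array(initial_y(cell_type))


def ep_rates(state: EpState, params: EpParams, i_stim: float = 0.0
             ) -> tuple[dict, CurrentSet]:
    """Time derivatives of all electrophysiology state entries except
    [Ca2+]i (owned by the coupled balance), plus all currents/fluxes.

    dV/dt equals -(sum of ionic currents + I_stim) exactly.
    """
    state.validate()
    y = state.to_array()
    prm = pack_params(params, MmParams())
    tab = build_table(params, 0.01)
    dy = np.empty(c.NY)
    cur = np.empty(c.N_CUR)
    ginf = np.empty(c.N_GATES)
    grlf = np.empty(c.N_GATES)
    k.core(y, prm, tab, i_stim, 1, dy, cur, ginf, grlf)
    rates = {n: float(dy[i]) for n, i in _EP_FIELDS if n != "cai"}
    return rates, CurrentSet.from_kernel(cur)
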