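"""Parameter containers for the coupled ventricular cell model.

``EpParams`` carries the electrophysiology constants (maximal
conductances, compartment geometry, buffers, CaMK), ``MmParams`` the
myofilament constants (crossbridge rates, passive titin/collagen
elements, metabolite levels).  Both are plain dataclasses; the numba
kernels consume a single flat float64 array produced by
:func:`pack_params`.

Baseline values follow the published human ventricular epicardial /
mid-myocardial / endocardial formulations of the source electrophysiology
model and the approximate crossbridge-cycling myofilament model; only
multiplicative remodeling factors are applied on top of these (see
:mod:`cardioem.remodeling`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from . import constants as c

ENDO, EPI, MCELL = "ENDO", "EPI", "MCELL"
CELL_TYPES = (ENDO, EPI, MCELL)
_CELLTYPE_CODE = {ENDO: 0.0, EPI: 1.0, MCELL: 2.0}

# cell geometry: cylinder of length 0.01 cm, radius 0.0011 cm
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * math.pi * _RAD * _RAD * _L          # uL
_AGEO = 2.0 * math.pi * _RAD * _RAD + 2.0 * math.pi * _RAD * _L
_ACAP = 2.0 * _AGEO                                   # cm^2


@dataclass
class EpParams:
    """Electrophysiology constants (units: mM, mV, ms, uA/uF, uL, cm^2)."""

    celltype: str = ENDO
    # extracellular milieu
    nao: float = 140.0
    cao: float = 1.8
    ko: float = 5.4
    # physical constants
    rgas: float = 8314.0        # J / (kmol K)
    temp: float = 310.0         # K
    frdy: float = 96485.0       # C / mol
    # compartment geometry
    acap: float = _ACAP
    vmyo: float = 0.68 * _VCELL
    vnsr: float = 0.0552 * _VCELL
    vjsr: float = 0.0048 * _VCELL
    vss: float = 0.02 * _VCELL
    # maximal conductances / permeabilities (ENDO baseline; cell-type
    # variants applied by for_cell_type)
    gna: float = 75.0
    gnal: float = 0.0075
    gto: float = 0.02
    pca: float = 0.0001
    gkr: float = 0.046
    gks: float = 0.0034
    gk1: float = 0.1908
    gncx: float = 0.0008
    pnak: float = 30.0
    gkb: float = 0.003
    pnab: float = 3.75e-10
    pcab: float = 2.5e-8
    gpca: float = 0.0005
    # CaMK
    kmcamk: float = 0.15
    acamk: float = 0.05
    bcamk: float = 0.00068
    camko: float = 0.05
    kmcam: float = 0.0015
    camka_scale: float = 1.0
    # SR flux scalings (remodeling hooks; cell-type up-scaling folded in)
    upscale: float = 1.0
    leak_scale: float = 1.0
    jrel_scale: float = 1.0
    jrelnp_scale: float = 1.0
    thl_factor: float = 1.0     # scales the late-Na inactivation tau
    # late Na inactivation baseline time constant (ms)
    thl: float = 200.0
    # buffers
    cmdn: float = 0.05
    kmcmdn: float = 0.00238
    trpn: float = 0.07
    kmtrpn: float = 0.0005
    bsr: float = 0.047
    kmbsr: float = 0.00087
    bsl: float = 1.124
    kmbsl: float = 0.0087
    csqn: float = 10.0
    kmcsqn: float = 0.8

    def for_cell_type(self, celltype: str) -> "EpParams":
        """Return a copy with the published transmural conductance variants."""
        if celltype not in CELL_TYPES:
            raise ValueError(
                f"unknown cell type {celltype!r}; valid: {CELL_TYPES}")
        p = replace(self, celltype=celltype)
        if celltype == EPI:
            p.gnal *= 0.6
            p.gto *= 4.0
            p.pca *= 1.2
            p.gkr *= 1.3
            p.gks *= 1.4
            p.gk1 *= 1.2
            p.gncx *= 1.1
            p.pnak *= 0.9
            p.gkb *= 0.6
            p.upscale *= 1.3
            p.cmdn *= 1.3
        elif celltype == MCELL:
            p.gto *= 4.0
            p.pca *= 2.5
            p.gkr *= 0.8
            p.gk1 *= 1.3
            p.gncx *= 1.4
            p.pnak *= 0.7
            p.jrel_scale *= 1.7
        return p


@dataclass
class MmParams:
    """Myofilament constants (rates in 1/ms at 37 C, lengths in um,
    forces normalised to the maximal isometric crossbridge force)."""

    # troponin Ca binding
    tropconc: float = 70.0      # uM
    kon: float = 0.05           # 1/(uM ms)
    koffl: float = 0.25
    koffh: float = 0.025
    perm50: float = 0.5
    nperm: float = 15.0
    knp: float = 0.5
    kpn: float = 0.05
    # crossbridge cycling
    fapp: float = 0.5
    gapp: float = 0.07
    gslmod: float = 6.0
    hfxb: float = 2.0
    hfmdc: float = 5.0
    hbxb: float = 0.4
    hbmdc: float = 0.0
    gxb: float = 0.07
    sigmap: float = 8.0
    sigman: float = 1.0
    # species scaling of the crossbridge cycling rates: the source
    # myofilament model is parameterised for rat (1.0) with 0.2 for the
    # slower rabbit kinetics; human twitches are slower still, so the
    # human default keeps 0.2 (steady-state force is unaffected).
    xbmodsp: float = 0.2
    # strain / force / sarcomere-length dynamics
    x0: float = 0.007
    xpsi: float = 2.0
    kxb: float = 120.0
    visc: float = 3.0       # normalised force * ms / um
    mass: float = 50.0      # normalised force * ms^2 / um
    slrest: float = 1.85
    slset: float = 1.9
    slmin: float = 1.4
    slmax: float = 2.4
    lthin: float = 1.2
    lthick: float = 1.65
    lhbare: float = 0.1
    # passive elements
    pcont: float = 0.002
    pexpt: float = 10.0
    slc: float = 2.25
    pconc: float = 0.02
    pexpc: float = 70.0
    # metabolites (normal physiological defaults)
    mgatp: float = 5.0          # mM
    mgadp: float = 0.036        # mM
    pi_c: float = 2.0           # mM
    ph: float = 7.15
    kmatp: float = 0.5
    kmadp: float = 4.0
    kpi: float = 4.0

    @property
    def ss_duty(self) -> tuple[float, float]:
        """Steady-state pre/post-rotation fractions at optimal overlap,
        used for force normalisation and the bound-fraction estimate."""
        return _duty(self.fapp, self.gapp, self.hfxb, self.hbxb, self.gxb)


def pack_params(ep: EpParams, mm: MmParams) -> np.ndarray:
    """Flatten the two parameter sets into the kernel parameter array.

    The metabolite sensitivity of the crossbridge cycle is folded in
    here as multiplicative rate modifiers (ATP saturation of detachment,
    Pi promotion of powerstroke reversal, proton competition on troponin
    Ca affinity); all are ~1 at the normal metabolite defaults.
    """
    prm = np.zeros(c.NP_PARAMS)
    d = {**asdict(ep), **asdict(mm)}
    d["celltype"] = _CELLTYPE_CODE[ep.celltype]
    f_atp = mm.mgatp / (mm.mgatp + mm.kmatp * (1.0 + mm.mgadp / mm.kmadp))
    f_pi = 1.0 + mm.pi_c / mm.kpi
    f_h = 10.0 ** (7.15 - mm.ph)
    d["gxb"] = mm.gxb * f_atp
    d["hbxb"] = mm.hbxb * f_pi
    d["koffl"] = mm.koffl * f_h
    d["koffh"] = mm.koffh * f_h
    ssprer, sspostr = _duty(mm.fapp, mm.gapp, mm.hfxb, d["hbxb"], d["gxb"])
    d["ssxbprer"], d["ssxbpostr"] = ssprer, sspostr
    for name, idx in c.PARAM_INDEX.items():
        prm[idx] = d[name]
    return prm


def _duty(f: float, g: float, hf: float, hb: float, gx: float):
    """Steady-state pre/post-rotation crossbridge fractions."""
    den = gx * hf + f * hf + gx * g + hb * f + hb * g + gx * f
    return (hb * f + gx * f) / den, f * hf / den


def validate_ep(ep: EpParams) -> None:
    for name in ("gna", "gnal", "gto", "pca", "gkr", "gks", "gk1", "gncx",
                 "pnak", "gkb", "pnab", "pcab", "gpca"):
        if getattr(ep, name) < 0:
            raise ValueError(f"conductance {name} must be >= 0")
    for name in ("vmyo", "vnsr", "vjsr", "vss"):
        if getattr(ep, name) <= 0:
            raise ValueError(f"volume {name} must be > 0")
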