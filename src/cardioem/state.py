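"""Initial conditions for the coupled cell.

Electrophysiology entries are the published resting initial conditions of
the source human ventricular model (all three transmural cell types start
from the same vector and re-equilibrate their conductance-dependent
entries during pre-pacing); myofilament entries start relaxed at the
preload sarcomere length.
"""

from __future__ import annotations

import numpy as np

from . import constants as c

# resting state after prolonged quiescence (endocardial baseline)
_EP_INIT = {
    c.Y_V: -87.5,
    c.Y_NAI: 7.268,
    c.Y_NASS: 7.268,
    c.Y_KI: 144.65,
    c.Y_KSS: 144.65,
    c.Y_CAI: 8.6e-5,
    c.Y_CASS: 8.49e-5,
    c.Y_CANSR: 1.61,
    c.Y_CAJSR: 1.56,
    c.Y_M: 0.0074,
    c.Y_HF: 0.695,
    c.Y_HS: 0.695,
    c.Y_J: 0.695,
    c.Y_HSP: 0.452,
    c.Y_JP: 0.695,
    c.Y_ML: 0.00019,
    c.Y_HL: 0.497,
    c.Y_HLP: 0.265,
    c.Y_A: 0.001,
    c.Y_IF: 0.9995,
    c.Y_IS: 0.5865,
    c.Y_AP: 0.00051,
    c.Y_IFP: 0.9995,
    c.Y_ISP: 0.6393,
    c.Y_D: 2.34e-9,
    c.Y_FF: 1.0,
    c.Y_FS: 0.91,
    c.Y_FCAF: 1.0,
    c.Y_FCAS: 0.9998,
    c.Y_JCA: 1.0,
    c.Y_FFP: 1.0,
    c.Y_FCAFP: 1.0,
    c.Y_NCA: 0.00275,
    c.Y_XRF: 8.26e-6,
    c.Y_XRS: 0.453,
    c.Y_XS1: 0.2707,
    c.Y_XS2: 0.000192,
    c.Y_XK1: 0.9968,
    c.Y_JRELNP: 2.5e-7,
    c.Y_JRELP: 3.12e-7,
    c.Y_CAMKT: 0.0125,
}

_MM_INIT = {
    c.Y_N: 0.99,
    c.Y_XBPRER: 1e-4,
    c.Y_XBPOSTR: 1e-5,
    c.Y_XXBPRER: 0.0,
    c.Y_XXBPOSTR: 0.007,
    c.Y_TRPNL: 0.0147,
    c.Y_TRPNH: 0.13,
    c.Y_NNOXB: 0.99,
    c.Y_SL: 1.9,
    c.Y_VSL: 0.0,
}


def initial_y(celltype: str = "ENDO") -> np.ndarray:
    """Flat initial state vector (identical across cell types before
    re-equilibration by pre-pacing)."""
    y = np.zeros(c.NY)
    for i, val in _EP_INIT.items():
        y[i] = val
    for i, val in _MM_INIT.items():
        y[i] = val
    return y
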