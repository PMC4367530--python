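"""Voltage-dependent rate table for the electrophysiology sub-model.

All purely voltage-dependent quantities (gate steady states and time
constants, rectification factors, GHK flux coefficients, exchanger and
pump voltage factors) are tabulated on a uniform membrane-potential grid
and linearly interpolated inside the numba kernels.  The formulations
are the published human ventricular (endo/epi/M) rate equations; the
only modification hook is the late-Na inactivation time-constant factor
used by the heart-failure variants.

Tables are built per (cell type, tau_hL factor, time step): the third
column of every gate block stores exp(-dt/tau) so the Rush-Larsen
update needs no exponentials at run time.
"""

from __future__ import annotations

import numpy as np

from . import constants as c
from .params import EpParams, EPI, MCELL


def build_table(ep: EpParams, dt: float) -> np.ndarray:
    """Return the (N_V, N_TCOLS) lookup table for parameters ``ep``.

    ``dt`` is the fixed step the Rush-Larsen factors are built for.
    """
    v = np.linspace(c.V_MIN, c.V_MAX, c.N_V)
    tab = np.zeros((c.N_V, c.N_TCOLS))
    ko = ep.ko
    vfrt = v * ep.frdy / (ep.rgas * ep.temp)
    vffrt = v * ep.frdy * ep.frdy / (ep.rgas * ep.temp)

    inf = {}
    tau = {}

    # --- fast Na+ current gating
    inf["m"] = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    tau["m"] = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                      + 8.552 * np.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    inf["hf"] = hss
    inf["hs"] = hss
    tau["hf"] = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                       + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * np.exp((v + 5.730) / 56.66))
    tau["hs"] = ths
    inf["j"] = hss
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * np.exp((v + 0.9941) / 38.45))
    tau["j"] = tj
    inf["hsp"] = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    tau["hsp"] = 3.0 * ths
    inf["jp"] = hss
    tau["jp"] = 1.46 * tj

    # --- late Na+ current gating (tau_hL remodeling hook)
    inf["ml"] = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    tau["ml"] = tau["m"]
    inf["hl"] = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    thl = ep.thl * ep.thl_factor
    tau["hl"] = np.full_like(v, thl)
    inf["hlp"] = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    tau["hlp"] = np.full_like(v, 3.0 * thl)

    # --- transient outward K+ current gating
    inf["a"] = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    tau["a"] = 1.0515 / (
        1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    inf["if"] = iss
    inf["is"] = iss
    if ep.celltype == EPI:
        delta_epi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))
    else:
        delta_epi = np.ones_like(v)
    tif = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tis = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    tau["if"] = tif * delta_epi
    tau["is"] = tis * delta_epi
    inf["ap"] = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    tau["ap"] = tau["a"]
    dti_develop = 1.354 + 1e-4 / (np.exp((v - 167.4) / 15.89)
                                  + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    inf["ifp"] = iss
    inf["isp"] = iss
    tau["ifp"] = dti_develop * dti_recover * tau["if"]
    tau["isp"] = dti_develop * dti_recover * tau["is"]

    # --- L-type Ca2+ current gating
    inf["d"] = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    tau["d"] = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0))
                            + np.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    inf["ff"] = fss
    inf["fs"] = fss
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    tau["ff"] = tff
    tau["fs"] = tfs
    inf["fcaf"] = fss
    inf["fcas"] = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    tau["fcaf"] = tfcaf
    tau["fcas"] = tfcas
    inf["jca"] = fss
    tau["jca"] = np.full_like(v, 75.0)
    inf["ffp"] = fss
    tau["ffp"] = 2.5 * tff
    inf["fcafp"] = fss
    tau["fcafp"] = 2.5 * tfcaf

    # --- rapid delayed rectifier gating
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    inf["xrf"] = xrss
    inf["xrs"] = xrss
    tau["xrf"] = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                                + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    tau["xrs"] = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                                + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))

    # --- slow delayed rectifier gating
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    inf["xs1"] = xs1ss
    tau["xs1"] = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                                + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    inf["xs2"] = xs1ss
    tau["xs2"] = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                        + 0.0193 * np.exp(-(v + 66.54) / 31.0))

    # --- inward rectifier gating
    inf["xk1"] = 1.0 / (1.0 + np.exp(
        -(v + 2.5538 * ko + 144.59) / (1.5692 * ko + 3.8115)))
    tau["xk1"] = 122.2 / (np.exp(-(v + 127.2) / 20.36)
                          + np.exp((v + 236.8) / 69.33))

    order = ["m", "hf", "hs", "j", "hsp", "jp", "ml", "hl", "hlp",
             "a", "if", "is", "ap", "ifp", "isp",
             "d", "ff", "fs", "fcaf", "fcas", "jca", "ffp", "fcafp",
             "xrf", "xrs", "xs1", "xs2", "xk1"]
    assert len(order) == c.N_GATES
    for g, name in enumerate(order):
        tab[:, 3 * g] = inf[name]
        tab[:, 3 * g + 1] = tau[name]
        tab[:, 3 * g + 2] = np.exp(-dt / tau[name])

    # --- instantaneous voltage factors
    tab[:, c.T_RKR] = (1.0 / (1.0 + np.exp((v + 55.0) / 75.0))
                       * 1.0 / (1.0 + np.exp((v - 10.0) / 30.0)))
    tab[:, c.T_XKB] = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    tab[:, c.T_RK1] = 1.0 / (1.0 + np.exp(
        (v + 105.8 - 2.6 * ko) / 9.493))
    tab[:, c.T_HCA] = np.exp(0.1670 * vfrt)
    tab[:, c.T_HNA] = np.exp(0.5224 * vfrt)
    tab[:, c.T_KNAI] = 9.073 * np.exp(-0.1550 * vfrt / 3.0)
    tab[:, c.T_KNAO] = 27.78 * np.exp((1.0 + 0.1550) * vfrt / 3.0)

    # --- GHK coefficients: flux = A * c_in - B * (partition * c_out)
    vs = np.where(np.abs(v) < 1e-6, 1e-6, v)
    vfrt_s = vs * ep.frdy / (ep.rgas * ep.temp)
    vffrt_s = vs * ep.frdy * ep.frdy / (ep.rgas * ep.temp)
    e2 = np.exp(2.0 * vfrt_s)
    e1 = np.exp(vfrt_s)
    tab[:, c.T_ACAL] = 4.0 * vffrt_s * e2 / (e2 - 1.0)
    tab[:, c.T_BCAL] = 4.0 * vffrt_s / (e2 - 1.0)
    tab[:, c.T_ACANA] = vffrt_s * e1 / (e1 - 1.0)
    tab[:, c.T_BCANA] = vffrt_s / (e1 - 1.0)

    # --- fast/slow component splits
    tab[:, c.T_AFCAF] = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    tab[:, c.T_AXRF] = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    tab[:, c.T_AIF] = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    return tab
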