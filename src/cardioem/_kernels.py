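"""Numba kernels for the coupled electromechanical cell.

One flat state vector (see :mod:`cardioem.constants`), one flat parameter
array, one voltage lookup table.  ``core`` evaluates all currents, fluxes
and state derivatives; ``step`` advances one fixed step with the
Rush-Larsen scheme for the gates (exact exponential update using the
tabulated factors) and forward Euler elsewhere, with exact exponential
updates for the three linear-in-state variables whose time constants can
collapse (SR release ramps, the Ca-dependent ICaL mode fraction).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import *  # noqa: F401,F403 - index constants


@njit(cache=True, fastmath=True)
def _ncx_flux(ca, na, nao, cao, hca, hna):
    """Na/Ca exchanger turnover (shared by myoplasmic and subspace
    components); returns allo * (J_Na + 2 J_Ca)."""
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    h1 = 1.0 + na / kna3 * (1.0 + hna)
    h2 = (na * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + na / kna1 * (1.0 + na / kna2)
    h5 = na * na / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * ca * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    e1 = x1 / s
    e2 = x2 / s
    e3 = x3 / s
    e4 = x4 / s
    allo = 1.0 / (1.0 + (150.0e-6 / ca) ** 2)
    jna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jca = e2 * k2 - e1 * k1
    return allo * (jna + 2.0 * jca)


@njit(cache=True, fastmath=True)
def _nak_pump(knai, knao, nai, ki, nao, ko):
    """Na/K-ATPase turnover; returns 3 J_Na + 2 J_K (per unit Pnak)."""
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    kki = 0.5
    kko = 0.3582
    mgadp = 0.05
    mgatp = 9.8
    kmgatp = 1.698e-7
    hh = 1.0e-7
    ep = 4.2
    khp = 1.698e-7
    knap = 224.0
    kxkur = 292.0
    pp = ep / (1.0 + hh / khp + nai / knap + ki / kxkur)
    d_i = (1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0
    d_o = (1.0 + nao / knao) ** 3 + (1.0 + ko / kko) ** 2 - 1.0
    a1 = k1p * (nai / knai) ** 3 / d_i
    b1 = k1m * mgadp
    a2 = k2p
    b2 = k2m * (nao / knao) ** 3 / d_o
    a3 = k3p * (ko / kko) ** 2 / d_o
    b3 = k3m * pp * hh / (1.0 + mgatp / kmgatp)
    a4 = k4p * mgatp / kmgatp / (1.0 + mgatp / kmgatp)
    b4 = k4m * (ki / kki) ** 2 / d_i
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    s = x1 + x2 + x3 + x4
    e1 = x1 / s
    e2 = x2 / s
    e3 = x3 / s
    e4 = x4 / s
    return 3.0 * (e1 * a3 - e2 * b3) + 2.0 * (e4 * b1 - e3 * a1)


@njit(cache=True, fastmath=True)
def _overlap(sl, lthin, lthick, lhbare):
    """Thick/thin filament single-overlap fractions and d(overlap)/dSL."""
    half = 0.5 * sl
    if half < 0.5 * lthick:
        sovr_ze = half
        dze = 0.5
    else:
        sovr_ze = 0.5 * lthick
        dze = 0.0
    cle = lthin - half
    if cle > 0.5 * lhbare:
        sovr_cle = cle
        dcle = -0.5
    else:
        sovr_cle = 0.5 * lhbare
        dcle = 0.0
    len_sovr = sovr_ze - sovr_cle
    dlen = dze - dcle
    sovf_thick = 2.0 * len_sovr / (lthick - lhbare)
    sovf_thin = len_sovr / lthin
    dthin = dlen / lthin
    return sovf_thick, sovf_thin, dthin


@njit(cache=True, fastmath=True)
def _rice(y, prm, cai_um, iso):
    """Myofilament (crossbridge cycling) derivatives.

    Returns (dN, dXBprer, dXBpostr, dxprer, dxpostr, dTRPNL, dTRPNH,
    dNNoXB, dSL, dvSL, J_Trop [uM/ms], F_active, F_passive), all forces
    normalised to the maximal control isometric crossbridge force.
    """
    nxb = y[Y_N]
    xbprer = y[Y_XBPRER]
    xbpostr = y[Y_XBPOSTR]
    xprer = y[Y_XXBPRER]
    xpostr = y[Y_XXBPOSTR]
    trpnl = y[Y_TRPNL]
    trpnh = y[Y_TRPNH]
    nnoxb = y[Y_NNOXB]
    sl = y[Y_SL]
    vsl = 0.0 if iso == 1 else y[Y_VSL]

    x0 = prm[P_X0]
    sovf_thick, sovf_thin, dthin_dsl = _overlap(
        sl, prm[P_LTHIN], prm[P_LTHICK], prm[P_LHBARE])

    # troponin Ca binding
    kon = prm[P_KON]
    dtrpnl = kon * cai_um * (1.0 - trpnl) - prm[P_KOFFL] * trpnl
    dtrpnh = kon * cai_um * (1.0 - trpnh) - prm[P_KOFFH] * trpnh

    # regulatory-unit permissiveness (strongly cooperative)
    tropreg = (1.0 - sovf_thin) * trpnl + sovf_thin * trpnh
    r = prm[P_PERM50] / tropreg
    r3 = r * r * r
    r15 = r3 * r3 * r3 * r3 * r3           # nperm = 15
    permtot = np.sqrt(1.0 / (1.0 + r15))
    inprmt = 1.0 / permtot
    if inprmt > 100.0:
        inprmt = 100.0
    knpt = prm[P_KNP] * permtot
    kpnt = prm[P_KPN] * inprmt

    # crossbridge transition rates with SL and strain dependence
    xbm = prm[P_XBMODSP]
    fappt = prm[P_FAPP] * xbm
    gappt = prm[P_GAPP] * (1.0 + (1.0 - sovf_thick) * prm[P_GSLMOD]) * xbm
    arg = -np.sign(xprer) * prm[P_HFMDC] * (xprer / x0) ** 2
    if arg > 50.0:
        arg = 50.0
    hfmd = np.exp(arg)
    hft = prm[P_HFXB] * hfmd * xbm
    hbt = prm[P_HBXB] * xbm
    if xpostr < x0:
        arg = prm[P_SIGMAP] * ((x0 - xpostr) / x0) ** 2
    else:
        arg = prm[P_SIGMAN] * ((xpostr - x0) / x0) ** 2
    if arg > 50.0:
        arg = 50.0
    gxbt = prm[P_GXB] * np.exp(arg) * xbm

    pxb = 1.0 - nxb - xbprer - xbpostr
    dn = -knpt * nxb + kpnt * pxb
    dxbprer = fappt * pxb - (gappt + hft) * xbprer + hbt * xbpostr
    dxbpostr = hft * xbprer - (hbt + gxbt) * xbpostr
    dnnoxb = -knpt * nnoxb + kpnt * (1.0 - nnoxb)

    # mean-distortion dynamics
    den = (fappt * hft + gxbt * hft + gxbt * gappt + hbt * fappt
           + hbt * gappt + gxbt * fappt)
    dtyprer = (hbt * fappt + gxbt * fappt) / den
    dtypostr = fappt * hft / den
    xpsi = prm[P_XPSI]
    dxprer = 0.5 * vsl + (xpsi / dtyprer) * (
        -fappt * xprer + hbt * (xpostr - x0 - xprer))
    dxpostr = 0.5 * vsl + (xpsi / dtypostr) * hft * (xprer + x0 - xpostr)

    # forces (normalised to kxb * x0 * SSXBpostr)
    fnorm = x0 * prm[P_SSXBPOSTR]
    f_active = sovf_thick * (xpostr * xbpostr + xprer * xbprer) / fnorm
    ds = sl - prm[P_SLREST]
    f_titin = np.sign(ds) * prm[P_PCONT] * (
        np.exp(prm[P_PEXPT] * np.abs(ds)) - 1.0)
    if sl > prm[P_SLC]:
        f_coll = prm[P_PCONC] * (np.exp(prm[P_PEXPC] * (sl - prm[P_SLC]))
                                 - 1.0)
    else:
        f_coll = 0.0
    f_passive = f_titin + f_coll

    # unloaded sarcomere-length dynamics (preload set by SLset)
    if iso == 1:
        dsl = 0.0
        dvsl = 0.0
    else:
        dpre = prm[P_SLSET] - prm[P_SLREST]
        f_preload = np.sign(dpre) * prm[P_PCONT] * (
            np.exp(prm[P_PEXPT] * np.abs(dpre)) - 1.0)
        dsl = vsl
        dvsl = (f_preload - f_active - f_passive
                - prm[P_VISC] * vsl) / prm[P_MASS]
        if (sl <= prm[P_SLMIN] and dsl < 0.0) or \
           (sl >= prm[P_SLMAX] and dsl > 0.0):
            dsl = 0.0
            dvsl = 0.0

    # net Ca flux onto troponin (uM/ms), including the overlap-weighted
    # redistribution between bound and unbound regulatory units
    ssprer = prm[P_SSXBPRER]
    sspostr = prm[P_SSXBPOSTR]
    frsbxb = (xbpostr + xbprer) / (sspostr + ssprer)
    dfrsbxb = (dxbpostr + dxbprer) / (sspostr + ssprer)
    dsovf_thin = dthin_dsl * dsl
    trop_conc = prm[P_TROPCONC]
    jtrop = trop_conc * (
        (1.0 - sovf_thin) * dtrpnl
        + sovf_thin * (frsbxb * dtrpnh + (1.0 - frsbxb) * dtrpnl)
        + dsovf_thin * (frsbxb * trpnh + (1.0 - frsbxb) * trpnl - trpnl)
        + sovf_thin * dfrsbxb * (trpnh - trpnl))
    return (dn, dxbprer, dxbpostr, dxprer, dxpostr, dtrpnl, dtrpnh,
            dnnoxb, dsl, dvsl, jtrop, f_active, f_passive)


@njit(cache=True, fastmath=True)
def core(y, prm, tab, istim, iso, dy, cur, ginf, grlf):
    """Evaluate all derivatives, currents and fluxes at state ``y``.

    Fills ``dy`` (NY), ``cur`` (N_CUR), ``ginf``/``grlf`` (N_GATES).
    """
    v = y[Y_V]
    nai = y[Y_NAI]
    nass = y[Y_NASS]
    ki = y[Y_KI]
    kss = y[Y_KSS]
    cai = y[Y_CAI]
    cass = y[Y_CASS]
    cansr = y[Y_CANSR]
    cajsr = y[Y_CAJSR]

    # --- table lookup
    x = (v - V_MIN) / DV
    if x < 0.0:
        x = 0.0
    elif x > N_V - 1.001:
        x = N_V - 1.001
    i0 = int(x)
    w = x - i0
    row0 = tab[i0]
    row1 = tab[i0 + 1]
    for g in range(N_GATES):
        ginf[g] = row0[3 * g] + w * (row1[3 * g] - row0[3 * g])
        grlf[g] = row0[3 * g + 2] + w * (row1[3 * g + 2] - row0[3 * g + 2])

    def lk(col):
        return row0[col] + w * (row1[col] - row0[col])

    rkr = lk(T_RKR)
    xkb = lk(T_XKB)
    rk1 = lk(T_RK1)
    hca = lk(T_HCA)
    hna = lk(T_HNA)
    knai = lk(T_KNAI)
    knao = lk(T_KNAO)
    acal = lk(T_ACAL)
    bcal = lk(T_BCAL)
    acana = lk(T_ACANA)
    bcana = lk(T_BCANA)
    afcaf = lk(T_AFCAF)
    axrf = lk(T_AXRF)
    aif = lk(T_AIF)

    nao = prm[P_NAO]
    cao = prm[P_CAO]
    ko = prm[P_KO]
    rtf = prm[P_RGAS] * prm[P_TEMP] / prm[P_FRDY]
    ena = rtf * np.log(nao / nai)
    ek = rtf * np.log(ko / ki)
    pkna = 0.01833
    eks = rtf * np.log((ko + pkna * nao) / (ki + pkna * nai))

    # --- CaMK
    camkb = prm[P_CAMKO] * (1.0 - y[Y_CAMKT]) / (1.0 + prm[P_KMCAM] / cass)
    camka_raw = camkb + y[Y_CAMKT]
    camka = prm[P_CAMKA_SCALE] * camka_raw
    dy[Y_CAMKT] = (prm[P_ACAMK] * camkb * camka_raw
                   - prm[P_BCAMK] * y[Y_CAMKT])
    kmcamk = prm[P_KMCAMK]
    fphos = 1.0 / (1.0 + kmcamk / camka)

    # --- INa (fast)
    h = 0.99 * y[Y_HF] + 0.01 * y[Y_HS]
    hp = 0.99 * y[Y_HF] + 0.01 * y[Y_HSP]
    m3 = y[Y_M] ** 3
    ina = prm[P_GNA] * (v - ena) * m3 * (
        (1.0 - fphos) * h * y[Y_J] + fphos * hp * y[Y_JP])

    # --- INaL
    inal = prm[P_GNAL] * (v - ena) * y[Y_ML] * (
        (1.0 - fphos) * y[Y_HL] + fphos * y[Y_HLP])

    # --- Ito
    i_gate = aif * y[Y_IF] + (1.0 - aif) * y[Y_IS]
    ip_gate = aif * y[Y_IFP] + (1.0 - aif) * y[Y_ISP]
    ito = prm[P_GTO] * (v - ek) * (
        (1.0 - fphos) * y[Y_A] * i_gate + fphos * y[Y_AP] * ip_gate)

    # --- ICaL / ICaNa / ICaK
    phical = acal * cass - bcal * 0.341 * cao
    phicana = acana * 0.75 * nass - bcana * 0.75 * nao
    phicak = acana * 0.75 * kss - bcana * 0.75 * ko
    f = 0.6 * y[Y_FF] + 0.4 * y[Y_FS]
    fp = 0.6 * y[Y_FFP] + 0.4 * y[Y_FS]
    fca = afcaf * y[Y_FCAF] + (1.0 - afcaf) * y[Y_FCAS]
    fcap = afcaf * y[Y_FCAFP] + (1.0 - afcaf) * y[Y_FCAS]
    nca = y[Y_NCA]
    d_g = y[Y_D]
    jca_g = y[Y_JCA]
    pca = prm[P_PCA]
    pcap = 1.1 * pca
    mode_np = d_g * (f * (1.0 - nca) + jca_g * fca * nca)
    mode_p = d_g * (fp * (1.0 - nca) + jca_g * fcap * nca)
    ical = ((1.0 - fphos) * pca * phical * mode_np
            + fphos * pcap * phical * mode_p)
    icana = ((1.0 - fphos) * 0.00125 * pca * phicana * mode_np
             + fphos * 0.00125 * pcap * phicana * mode_p)
    icak = ((1.0 - fphos) * 3.574e-4 * pca * phicak * mode_np
            + fphos * 3.574e-4 * pcap * phicak * mode_p)

    # nca kinetics (rate floor keeps the mode fraction well defined if
    # the jca gate is driven to zero)
    kmn = 0.002
    k2n = 1000.0
    km2n = jca_g * 1.0
    if km2n < 1e-8:
        km2n = 1e-8
    anca = 1.0 / (k2n / km2n + (1.0 + kmn / cass) ** 4)
    cur[C_NCA_INF] = anca * k2n / km2n
    cur[C_NCA_TAU] = 1.0 / km2n
    dy[Y_NCA] = anca * k2n - nca * km2n

    # --- IKr
    xr = axrf * y[Y_XRF] + (1.0 - axrf) * y[Y_XRS]
    ikr = prm[P_GKR] * np.sqrt(ko / 5.4) * xr * rkr * (v - ek)

    # --- IKs
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    iks = prm[P_GKS] * ksca * y[Y_XS1] * y[Y_XS2] * (v - eks)

    # --- IK1
    ik1 = prm[P_GK1] * np.sqrt(ko) * rk1 * y[Y_XK1] * (v - ek)

    # --- INaCa (myoplasmic + subspace)
    gncx = prm[P_GNCX]
    inaca_i = 0.8 * gncx * _ncx_flux(cai, nai, nao, cao, hca, hna)
    inaca_ss = 0.2 * gncx * _ncx_flux(cass, nass, nao, cao, hca, hna)

    # --- INaK
    inak = prm[P_PNAK] * _nak_pump(knai, knao, nai, ki, nao, ko)

    # --- background / pump currents
    ikb = prm[P_GKB] * xkb * (v - ek)
    inab = prm[P_PNAB] * (acana * nai - bcana * nao)
    icab = prm[P_PCAB] * (acal * cai - bcal * 0.341 * cao)
    ipca = prm[P_GPCA] * cai / (0.0005 + cai)

    # --- diffusion fluxes
    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0
    jdiff = (cass - cai) / 0.2

    # --- SR release
    bt = 4.75
    a_rel = 0.5 * bt
    reg = 1.0 / (1.0 + (1.5 / cajsr) ** 8)
    jrelnp_inf = prm[P_JREL_SCALE] * prm[P_JRELNP_SCALE] * a_rel * \
        (-ical) * reg
    tau_np = bt / (1.0 + 0.0123 / cajsr)
    if tau_np < 0.001:
        tau_np = 0.001
    btp = 1.25 * bt
    jrelp_inf = prm[P_JREL_SCALE] * 0.5 * btp * (-ical) * reg
    tau_p = btp / (1.0 + 0.0123 / cajsr)
    if tau_p < 0.001:
        tau_p = 0.001
    cur[C_JRELNP_INF] = jrelnp_inf
    cur[C_JRELNP_TAU] = tau_np
    cur[C_JRELP_INF] = jrelp_inf
    cur[C_JRELP_TAU] = tau_p
    dy[Y_JRELNP] = (jrelnp_inf - y[Y_JRELNP]) / tau_np
    dy[Y_JRELP] = (jrelp_inf - y[Y_JRELP]) / tau_p
    jrel = (1.0 - fphos) * y[Y_JRELNP] + fphos * y[Y_JRELP]

    # --- SR uptake and leak
    jupnp = prm[P_UPSCALE] * 0.004375 * cai / (cai + 0.00092)
    jupp = prm[P_UPSCALE] * 2.75 * 0.004375 * cai / (cai + 0.00092
                                                     - 0.00017)
    jleak = prm[P_LEAK_SCALE] * 0.0039375 * cansr / 15.0
    jup = (1.0 - fphos) * jupnp + fphos * jupp - jleak
    jtr = (cansr - cajsr) / 100.0

    # --- myofilament
    (dn, dxbprer, dxbpostr, dxprer, dxpostr, dtrpnl, dtrpnh, dnnoxb,
     dsl, dvsl, jtrop, f_active, f_passive) = _rice(
        y, prm, 1000.0 * cai, iso)
    dy[Y_N] = dn
    dy[Y_XBPRER] = dxbprer
    dy[Y_XBPOSTR] = dxbpostr
    dy[Y_XXBPRER] = dxprer
    dy[Y_XXBPOSTR] = dxpostr
    dy[Y_TRPNL] = dtrpnl
    dy[Y_TRPNH] = dtrpnh
    dy[Y_NNOXB] = dnnoxb
    dy[Y_SL] = dsl
    dy[Y_VSL] = dvsl
    cur[C_DVSL] = dvsl

    # --- membrane potential
    itot = (ina + inal + ito + ical + icana + icak + ikr + iks + ik1
            + inaca_i + inaca_ss + inak + inab + ikb + ipca + icab)
    dy[Y_V] = -(itot + istim)

    acap = prm[P_ACAP]
    frdy = prm[P_FRDY]
    vmyo = prm[P_VMYO]
    vnsr = prm[P_VNSR]
    vjsr = prm[P_VJSR]
    vss = prm[P_VSS]

    # --- ionic concentration balances
    dy[Y_NAI] = (-(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab)
                 * acap / (frdy * vmyo) + jdiffna * vss / vmyo)
    dy[Y_NASS] = (-(icana + 3.0 * inaca_ss) * acap / (frdy * vss)
                  - jdiffna)
    dy[Y_KI] = (-(ito + ikr + iks + ik1 + ikb + istim - 2.0 * inak)
                * acap / (frdy * vmyo) + jdiffk * vss / vmyo)
    dy[Y_KSS] = -icak * acap / (frdy * vss) - jdiffk

    # cytosolic Ca: calmodulin-only buffer; troponin handled by J_Trop
    bcai = 1.0 / (1.0 + prm[P_CMDN] * prm[P_KMCMDN]
                  / (prm[P_KMCMDN] + cai) ** 2)
    dy[Y_CAI] = bcai * (
        -(ipca + icab - 2.0 * inaca_i) * acap / (2.0 * frdy * vmyo)
        - jup * vnsr / vmyo + jdiff * vss / vmyo - jtrop / 1000.0)

    bcass = 1.0 / (1.0 + prm[P_BSR] * prm[P_KMBSR]
                   / (prm[P_KMBSR] + cass) ** 2
                   + prm[P_BSL] * prm[P_KMBSL]
                   / (prm[P_KMBSL] + cass) ** 2)
    dy[Y_CASS] = bcass * (
        -(ical - 2.0 * inaca_ss) * acap / (2.0 * frdy * vss)
        + jrel * vjsr / vss - jdiff)
    dy[Y_CANSR] = jup - jtr * vjsr / vnsr
    bcajsr = 1.0 / (1.0 + prm[P_CSQN] * prm[P_KMCSQN]
                    / (prm[P_KMCSQN] + cajsr) ** 2)
    dy[Y_CAJSR] = bcajsr * (jtr - jrel)

    # --- gate derivatives (for the adaptive reference / rates API)
    gi = 0
    for s in range(Y_M, Y_FCAFP + 1):
        tau = row0[3 * gi + 1] + w * (row1[3 * gi + 1] - row0[3 * gi + 1])
        dy[s] = (ginf[gi] - y[s]) / tau
        gi += 1
    for s in range(Y_XRF, Y_XK1 + 1):
        tau = row0[3 * gi + 1] + w * (row1[3 * gi + 1] - row0[3 * gi + 1])
        dy[s] = (ginf[gi] - y[s]) / tau
        gi += 1

    cur[C_INA] = ina
    cur[C_INAL] = inal
    cur[C_ITO] = ito
    cur[C_ICAL] = ical
    cur[C_ICANA] = icana
    cur[C_ICAK] = icak
    cur[C_IKR] = ikr
    cur[C_IKS] = iks
    cur[C_IK1] = ik1
    cur[C_INACA_I] = inaca_i
    cur[C_INACA_SS] = inaca_ss
    cur[C_INAK] = inak
    cur[C_INAB] = inab
    cur[C_IKB] = ikb
    cur[C_IPCA] = ipca
    cur[C_ICAB] = icab
    cur[C_JDIFF] = jdiff
    cur[C_JDIFFNA] = jdiffna
    cur[C_JDIFFK] = jdiffk
    cur[C_JUP] = jup
    cur[C_JLEAK] = jleak
    cur[C_JREL] = jrel
    cur[C_JTR] = jtr
    cur[C_JTROP] = jtrop
    cur[C_F_ACTIVE] = f_active
    cur[C_F_PASSIVE] = f_passive
    cur[C_CAMKA] = camka


@njit(cache=True, fastmath=True)
def step(y, prm, tab, istim, dt, iso, dy, cur, ginf, grlf):
    """Advance one fixed step (Rush-Larsen gates + forward Euler)."""
    core(y, prm, tab, istim, iso, dy, cur, ginf, grlf)
    # gates: exact exponential update with tabulated factors
    gi = 0
    for s in range(Y_M, Y_FCAFP + 1):
        y[s] = ginf[gi] + (y[s] - ginf[gi]) * grlf[gi]
        gi += 1
    for s in range(Y_XRF, Y_XK1 + 1):
        y[s] = ginf[gi] + (y[s] - ginf[gi]) * grlf[gi]
        gi += 1
    # linear-in-state variables with state-dependent time constants
    e = np.exp(-dt / cur[C_JRELNP_TAU])
    y[Y_JRELNP] = cur[C_JRELNP_INF] + (y[Y_JRELNP]
                                       - cur[C_JRELNP_INF]) * e
    e = np.exp(-dt / cur[C_JRELP_TAU])
    y[Y_JRELP] = cur[C_JRELP_INF] + (y[Y_JRELP] - cur[C_JRELP_INF]) * e
    e = np.exp(-dt / cur[C_NCA_TAU])
    y[Y_NCA] = cur[C_NCA_INF] + (y[Y_NCA] - cur[C_NCA_INF]) * e
    # everything else: forward Euler
    y[Y_V] += dt * dy[Y_V]
    for s in range(Y_NAI, Y_CAJSR + 1):
        y[s] += dt * dy[s]
    y[Y_CAMKT] += dt * dy[Y_CAMKT]
    for s in range(Y_N, Y_VSL + 1):
        y[s] += dt * dy[s]


@njit(cache=True, fastmath=True)
def run_interval(y, prm, tab, dt, n_steps, stim_amp, stim_dur,
                 sample_every, rec, iso):
    """Integrate ``n_steps`` fixed steps, stimulating for ``stim_dur`` ms
    at interval start; record every ``sample_every`` steps into ``rec``
    (n_samples+1 rows, N_REC columns).  Returns -1 on success or the
    failing step index if the membrane potential became non-finite."""
    dy = np.empty(NY)
    cur = np.empty(N_CUR)
    ginf = np.empty(N_GATES)
    grlf = np.empty(N_GATES)
    k = 0
    for n in range(n_steps):
        t = n * dt
        istim = stim_amp if t < stim_dur else 0.0
        if n % sample_every == 0:
            core(y, prm, tab, istim, iso, dy, cur, ginf, grlf)
            _record(rec, k, t, y, cur)
            k += 1
        step(y, prm, tab, istim, dt, iso, dy, cur, ginf, grlf)
        if not np.isfinite(y[Y_V]):
            return n
    core(y, prm, tab, 0.0, iso, dy, cur, ginf, grlf)
    _record(rec, k, n_steps * dt, y, cur)
    return -1


@njit(cache=True, fastmath=True)
def _record(rec, k, t, y, cur):
    rec[k, R_T] = t
    rec[k, R_V] = y[Y_V]
    rec[k, R_CAI] = y[Y_CAI]
    rec[k, R_NAI] = y[Y_NAI]
    rec[k, R_KI] = y[Y_KI]
    rec[k, R_CANSR] = y[Y_CANSR]
    rec[k, R_CAJSR] = y[Y_CAJSR]
    rec[k, R_ICAL] = cur[C_ICAL]
    rec[k, R_INACA] = cur[C_INACA_I] + cur[C_INACA_SS]
    rec[k, R_INAK] = cur[C_INAK]
    rec[k, R_IPCA] = cur[C_IPCA]
    rec[k, R_JUP] = cur[C_JUP]
    rec[k, R_JLEAK] = cur[C_JLEAK]
    rec[k, R_JREL] = cur[C_JREL]
    rec[k, R_SL] = y[Y_SL]
    rec[k, R_FACT] = cur[C_F_ACTIVE]
    rec[k, R_FPAS] = cur[C_F_PASSIVE]
    rec[k, R_JTROP] = cur[C_JTROP]
    rec[k, R_CASS] = y[Y_CASS]


@njit(cache=True, fastmath=True)
def mm_step_clamped(y, prm, cai_um, dt, iso):
    """Advance the myofilament sub-model one step at clamped Ca."""
    (dn, dxbprer, dxbpostr, dxprer, dxpostr, dtrpnl, dtrpnh, dnnoxb,
     dsl, dvsl, jtrop, f_active, f_passive) = _rice(y, prm, cai_um, iso)
    y[Y_N] += dt * dn
    y[Y_XBPRER] += dt * dxbprer
    y[Y_XBPOSTR] += dt * dxbpostr
    y[Y_XXBPRER] += dt * dxprer
    y[Y_XXBPOSTR] += dt * dxpostr
    y[Y_TRPNL] += dt * dtrpnl
    y[Y_TRPNH] += dt * dtrpnh
    y[Y_NNOXB] += dt * dnnoxb
    y[Y_SL] += dt * dsl
    y[Y_VSL] += dt * dvsl
    return f_active, f_passive, jtrop


@njit(cache=True, fastmath=True)
def mm_relax_clamped(y, prm, cai_um, dt, t_max, iso, rel_tol):
    """Integrate the clamped-Ca myofilament model until the active force
    is stationary (relative change below ``rel_tol`` per ms) or ``t_max``
    is reached.  Returns (f_active, f_passive, converged)."""
    f_prev, f_pas = 0.0, 0.0
    check = int(round(1.0 / dt))      # compare once per ms
    n = int(round(t_max / dt))
    converged = False
    f_act = 0.0
    for i in range(n):
        f_act, f_pas, _ = mm_step_clamped(y, prm, cai_um, dt, iso)
        if (i + 1) % check == 0:
            scale = max(abs(f_act), 1e-9)
            if abs(f_act - f_prev) / scale < rel_tol:
                converged = True
                break
            f_prev = f_act
    return f_act, f_pas, converged


@njit(cache=True, fastmath=True)
def _gate_half(y, cur, ginf, grlf, dt_half):
    """Exponential half-step for gates and the linear SR-release /
    ICaL-mode variables (coefficients from the last ``core`` call;
    ``grlf`` must come from a table built for ``dt_half``)."""
    gi = 0
    for s in range(Y_M, Y_FCAFP + 1):
        y[s] = ginf[gi] + (y[s] - ginf[gi]) * grlf[gi]
        gi += 1
    for s in range(Y_XRF, Y_XK1 + 1):
        y[s] = ginf[gi] + (y[s] - ginf[gi]) * grlf[gi]
        gi += 1
    e = np.exp(-dt_half / cur[C_JRELNP_TAU])
    y[Y_JRELNP] = cur[C_JRELNP_INF] + (y[Y_JRELNP]
                                       - cur[C_JRELNP_INF]) * e
    e = np.exp(-dt_half / cur[C_JRELP_TAU])
    y[Y_JRELP] = cur[C_JRELP_INF] + (y[Y_JRELP] - cur[C_JRELP_INF]) * e
    e = np.exp(-dt_half / cur[C_NCA_TAU])
    y[Y_NCA] = cur[C_NCA_INF] + (y[Y_NCA] - cur[C_NCA_INF]) * e


# non-gate (forward-integrated) state indices for the symmetric scheme
_NG = np.array([Y_V, Y_NAI, Y_NASS, Y_KI, Y_KSS, Y_CAI, Y_CASS,
                Y_CANSR, Y_CAJSR, Y_CAMKT, Y_N, Y_XBPRER, Y_XBPOSTR,
                Y_XXBPRER, Y_XXBPOSTR, Y_TRPNL, Y_TRPNH, Y_NNOXB,
                Y_SL, Y_VSL])


@njit(cache=True, fastmath=True)
def step2(y, prm, tab_h, istim, dt, iso, dy, cur, ginf, grlf):
    """Symmetrised second-order step: exponential gate half-step,
    explicit midpoint for potential/concentrations/myofilament, gate
    half-step.  ``tab_h`` must be built for dt/2."""
    half = 0.5 * dt
    core(y, prm, tab_h, istim, iso, dy, cur, ginf, grlf)
    _gate_half(y, cur, ginf, grlf, half)
    # midpoint (RK2) for the non-gate states
    core(y, prm, tab_h, istim, iso, dy, cur, ginf, grlf)
    y0 = np.empty(_NG.size)
    for i in range(_NG.size):
        s = _NG[i]
        y0[i] = y[s]
        y[s] = y[s] + half * dy[s]
    core(y, prm, tab_h, istim, iso, dy, cur, ginf, grlf)
    for i in range(_NG.size):
        s = _NG[i]
        y[s] = y0[i] + dt * dy[s]
    # trailing gate half-step at the updated potential
    core(y, prm, tab_h, istim, iso, dy, cur, ginf, grlf)
    _gate_half(y, cur, ginf, grlf, half)


@njit(cache=True)
def react_nodes2(ystates, prm_by_type, tabs_h, types, dt, n_sub, istim):
    """Second-order reaction sub-step for tissue (see react_nodes)."""
    n_nodes = ystates.shape[0]
    dy = np.empty(NY)
    cur = np.empty(N_CUR)
    ginf = np.empty(N_GATES)
    grlf = np.empty(N_GATES)
    for i in range(n_nodes):
        y = ystates[i]
        ct = types[i]
        prm = prm_by_type[ct]
        tab = tabs_h[ct]
        for _ in range(n_sub):
            step2(y, prm, tab, istim[i], dt, 0, dy, cur, ginf, grlf)


@njit(cache=True)
def react_nodes(ystates, prm_by_type, tabs, types, dt, n_sub, istim):
    """Reaction sub-step for tissue: advance every node's cell model by
    ``n_sub`` steps of ``dt``.  ``ystates`` is (n_nodes, NY);
    ``prm_by_type`` (3, NP_PARAMS); ``tabs`` (3, N_V, N_TCOLS); ``types``
    int array of cell-type codes; ``istim`` per-node stimulus."""
    n_nodes = ystates.shape[0]
    dy = np.empty(NY)
    cur = np.empty(N_CUR)
    ginf = np.empty(N_GATES)
    grlf = np.empty(N_GATES)
    for i in range(n_nodes):
        y = ystates[i]
        ct = types[i]
        prm = prm_by_type[ct]
        tab = tabs[ct]
        for _ in range(n_sub):
            step(y, prm, tab, istim[i], dt, 0, dy, cur, ginf, grlf)
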