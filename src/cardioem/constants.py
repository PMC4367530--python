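"""Index layout shared by the numba kernels.

The coupled cell state is one flat float64 vector of length NY.  Entries
0-40 are the electrophysiology sub-model (membrane potential, gates,
concentrations, CaMK trap), 41-50 the myofilament sub-model (crossbridge
occupancies, mean distortions, troponin sites, sarcomere length and its
velocity).  Keeping a single vector lets the tissue code hold one
contiguous (n_nodes, NY) array.
"""

# ---------------------------------------------------------------- state
Y_V = 0
Y_NAI = 1
Y_NASS = 2
Y_KI = 3
Y_KSS = 4
Y_CAI = 5
Y_CASS = 6
Y_CANSR = 7
Y_CAJSR = 8
# fast/late Na and Ito / ICaL / IKr / IKs / IK1 gating (Rush-Larsen updated)
Y_M = 9
Y_HF = 10
Y_HS = 11
Y_J = 12
Y_HSP = 13
Y_JP = 14
Y_ML = 15
Y_HL = 16
Y_HLP = 17
Y_A = 18
Y_IF = 19
Y_IS = 20
Y_AP = 21
Y_IFP = 22
Y_ISP = 23
Y_D = 24
Y_FF = 25
Y_FS = 26
Y_FCAF = 27
Y_FCAS = 28
Y_JCA = 29
Y_FFP = 30
Y_FCAFP = 31
Y_NCA = 32          # L-type Ca-dependent inactivation mode fraction
Y_XRF = 33
Y_XRS = 34
Y_XS1 = 35
Y_XS2 = 36
Y_XK1 = 37
Y_JRELNP = 38
Y_JRELP = 39
Y_CAMKT = 40
# myofilament
Y_N = 41            # non-permissive regulatory units (overlap region)
Y_XBPRER = 42       # pre-rotation (weakly bound) crossbridges
Y_XBPOSTR = 43      # post-rotation (force generating) crossbridges
Y_XXBPRER = 44      # mean distortion of pre-rotation XBs (um)
Y_XXBPOSTR = 45     # mean distortion of post-rotation XBs (um)
Y_TRPNL = 46        # Ca occupancy, low-affinity troponin sites
Y_TRPNH = 47        # Ca occupancy, high-affinity troponin sites
Y_NNOXB = 48        # non-permissive units outside the overlap region
Y_SL = 49           # sarcomere length (um)
Y_VSL = 50          # d(SL)/dt (um/ms)

NY = 51

# gate states updated with the exponential (Rush-Larsen) scheme, in the
# order used by the voltage lookup table
RL_GATES = tuple(range(Y_M, Y_FCAFP + 1)) + tuple(range(Y_XRF, Y_XK1 + 1))
N_GATES = len(RL_GATES)  # 28

# ------------------------------------------------------------ parameters
_PARAM_NAMES = [
    # environment / geometry
    "celltype", "nao", "cao", "ko", "rgas", "temp", "frdy",
    "acap", "vmyo", "vnsr", "vjsr", "vss",
    # maximal conductances / permeabilities (cell-type factors folded in)
    "gna", "gnal", "gto", "pca", "gkr", "gks", "gk1", "gncx", "pnak",
    "gkb", "pnab", "pcab", "gpca",
    # CaMK
    "kmcamk", "acamk", "bcamk", "camko", "kmcam", "camka_scale",
    # SR flux scalings
    "upscale", "leak_scale", "jrel_scale", "jrelnp_scale",
    # buffers
    "cmdn", "kmcmdn", "trpn", "kmtrpn",
    "bsr", "kmbsr", "bsl", "kmbsl", "csqn", "kmcsqn",
    # myofilament: Ca binding / regulatory units
    "tropconc", "kon", "koffl", "koffh", "perm50", "nperm", "knp", "kpn",
    # myofilament: crossbridge cycling
    "fapp", "gapp", "gslmod", "hfxb", "hfmdc", "hbxb", "hbmdc", "gxb",
    "sigmap", "sigman", "xbmodsp",
    # myofilament: strain / force / SL dynamics
    "x0", "xpsi", "kxb", "visc", "mass",
    "slrest", "slset", "slmin", "slmax", "lthin", "lthick", "lhbare",
    "pcont", "pexpt", "slc", "pconc", "pexpc",
    # metabolites (Tran-style sensitivity, ~neutral at normal levels)
    "mgatp", "mgadp", "pi_c", "ph", "kmatp", "kmadp", "kpi",
    # precomputed steady-state duty fractions for force normalisation
    "ssxbprer", "ssxbpostr",
]

NP_PARAMS = len(_PARAM_NAMES)
PARAM_INDEX = {n: i for i, n in enumerate(_PARAM_NAMES)}

# expose P_<NAME> integer constants for the kernels
globals().update({f"P_{n.upper()}": i for i, n in enumerate(_PARAM_NAMES)})

# ------------------------------------------------------------ LUT layout
# per gate g: col 3g = steady state, 3g+1 = time constant,
# 3g+2 = exp(-dt/tau) for the dt the table was built with
T_EXTRA = 3 * N_GATES
T_RKR = T_EXTRA + 0      # IKr instantaneous rectification
T_XKB = T_EXTRA + 1      # IKb gating
T_RK1 = T_EXTRA + 2      # IK1 rectification
T_HCA = T_EXTRA + 3      # NCX exp(qca*v*F/RT)
T_HNA = T_EXTRA + 4      # NCX exp(qna*v*F/RT)
T_KNAI = T_EXTRA + 5     # INaK voltage-dependent Na affinity (intra)
T_KNAO = T_EXTRA + 6     # INaK voltage-dependent Na affinity (extra)
T_ACAL = T_EXTRA + 7     # GHK coefficients, divalent
T_BCAL = T_EXTRA + 8
T_ACANA = T_EXTRA + 9    # GHK coefficients, monovalent
T_BCANA = T_EXTRA + 10
T_AFCAF = T_EXTRA + 11   # fast/slow Ca-dependent inactivation split
T_AXRF = T_EXTRA + 12    # fast/slow IKr activation split
T_AIF = T_EXTRA + 13     # fast/slow Ito inactivation split

N_TCOLS = T_EXTRA + 14

V_MIN = -130.0
V_MAX = 90.0
N_V = 11001
DV = (V_MAX - V_MIN) / (N_V - 1)

# --------------------------------------------------------- trace columns
R_T = 0
R_V = 1
R_CAI = 2
R_NAI = 3
R_KI = 4
R_CANSR = 5
R_CAJSR = 6
R_ICAL = 7
R_INACA = 8
R_INAK = 9
R_IPCA = 10
R_JUP = 11
R_JLEAK = 12
R_JREL = 13
R_SL = 14
R_FACT = 15
R_FPAS = 16
R_JTROP = 17
R_CASS = 18
N_REC = 19

TRACE_COLUMNS = [
    "t", "v", "cai", "nai", "ki", "cansr", "cajsr", "ical", "inaca",
    "inak", "ipca", "jup", "jleak", "jrel", "sl", "f_active", "f_passive",
    "jtrop", "cass",
]

# ------------------------------------------------- current-set columns
CUR_NAMES = [
    "ina", "inal", "ito", "ical", "icana", "icak", "ikr", "iks", "ik1",
    "inaca_i", "inaca_ss", "inak", "inab", "ikb", "ipca", "icab",
    "jdiff", "jdiffna", "jdiffk", "jup", "jleak", "jrel", "jtr",
    "jtrop", "f_active", "f_passive", "camka",
    # auxiliary slots used by the integrator
    "jrelnp_inf", "jrelnp_tau", "jrelp_inf", "jrelp_tau",
    "nca_inf", "nca_tau", "dvsl",
]
N_CUR = len(CUR_NAMES)
CUR_INDEX = {n: i for i, n in enumerate(CUR_NAMES)}
globals().update({f"C_{n.upper()}": i for i, n in enumerate(CUR_NAMES)})
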