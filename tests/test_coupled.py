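"""Coupled cell: calcium-balance coupling, integrator behaviour,
steady-pacing phenotypes, trace round-trips."""

import numpy as np
import pytest

import cardioem.constants as c
from cardioem.coupled import (CoupledModel, TraceSet, beta_cai, d_cai,
                              pace)
from cardioem.ep import CurrentSet
from cardioem.params import EpParams, MmParams
from cardioem.protocols import apd, biomarkers_from_trace
from cardioem.state import initial_y


# ------------------------------------------------------------- beta_Cai
def test_beta_cai_limits_and_range():
    assert beta_cai(1e-4, 0.0, 0.00238) == 1.0
    assert beta_cai(10.0, 0.05, 0.00238) == pytest.approx(1.0, abs=1e-3)
    vals = [beta_cai(ca, 0.05, 0.00238)
            for ca in np.logspace(-5, -2, 30)]
    assert all(0.0 < v <= 1.0 for v in vals)


def test_beta_cai_at_half_saturation():
    # cai = Km: beta = 1/(1 + CMDN/(4 Km)) by direct substitution
    cmdn, km = 0.05, 0.00238
    assert beta_cai(km, cmdn, km) == pytest.approx(
        1.0 / (1.0 + cmdn / (4.0 * km)))


def test_beta_cai_rejects_nonpositive_calcium():
    with pytest.raises(ValueError):
        beta_cai(0.0, 0.05, 0.00238)


# ---------------------------------------------------------------- d_cai
def _currents(**kw):
    base = dict(ina=0, inal=0, ito=0, ical=0, ikr=0, iks=0, ik1=0,
                inaca_i=0, inaca_ss=0, inak=0, inab=0, icab=0, ipca=0,
                jup=0, jleak=0, jrel=0, jdiff=0)
    base.update(kw)
    return CurrentSet(**base)


def test_d_cai_zero_inputs_give_zero():
    assert d_cai(_currents(), 0.0, 1e-4, EpParams()) == 0.0


def test_d_cai_troponin_unit_bridge():
    # J_Trop is in uM/ms; with no buffering a flux of +1000 uM/ms
    # removes exactly 1 mM/ms from the cytosol
    ep = EpParams()
    ep.cmdn = 0.0
    assert d_cai(_currents(), 1000.0, 1e-4, ep) == pytest.approx(-1.0)


def test_d_cai_matches_term_by_term_oracle():
    """Independent re-evaluation of the calcium balance, term by term."""
    ep = EpParams()
    cur = _currents(ipca=0.012, icab=-0.03, inaca_i=-0.21, jup=3.1e-4,
                    jdiff=2.4e-4)
    jtrop = 37.0
    cai = 2.4e-4
    got = d_cai(cur, jtrop, cai, ep)
    # oracle: each term written out independently
    buffer_factor = 1.0 / (1.0 + ep.cmdn * ep.kmcmdn
                           / (ep.kmcmdn + cai) ** 2)
    sarcolemmal = -(0.012 + (-0.03) - 2.0 * (-0.21)) * ep.acap \
        / (2.0 * ep.frdy * ep.vmyo)
    uptake = -3.1e-4 * ep.vnsr / ep.vmyo
    diffusion = 2.4e-4 * ep.vss / ep.vmyo
    troponin = -37.0 / 1000.0
    expected = buffer_factor * (sarcolemmal + uptake + diffusion
                                + troponin)
    assert got == pytest.approx(expected, rel=1e-14)


def test_kernel_dcai_agrees_with_equation_oracle():
    """The compiled kernel's cytosolic-Ca rate equals the standalone
    d_cai evaluation built from the kernel's own currents."""
    m = CoupledModel(EpParams().for_cell_type("EPI"), MmParams(),
                     dt=0.01)
    y = initial_y("EPI")
    y[c.Y_V] = -20.0
    y[c.Y_CAI] = 3e-4
    dy, cur = m.rhs(y)
    gx = c.CUR_INDEX
    cs = _currents(ipca=cur[gx["ipca"]], icab=cur[gx["icab"]],
                   inaca_i=cur[gx["inaca_i"]], jup=cur[gx["jup"]],
                   jdiff=cur[gx["jdiff"]])
    expected = d_cai(cs, cur[gx["jtrop"]], y[c.Y_CAI], m.ep)
    assert dy[c.Y_CAI] == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------------------ integrator
def test_step_change_vanishes_with_dt():
    m = CoupledModel(EpParams().for_cell_type("ENDO"), MmParams(),
                     dt=0.01)
    s0 = m.initial_state()
    deltas = []
    for dt in (0.01, 0.001):
        m2 = CoupledModel(m.ep, m.mm, dt=dt)
        s1 = m2.step(s0)
        deltas.append(np.abs(s1.y - s0.y).max())
    assert deltas[1] < 0.2 * deltas[0]


def test_step_rejects_large_dt():
    with pytest.raises(ValueError):
        CoupledModel(EpParams(), MmParams(), dt=0.1)


def test_apd_converges_under_step_halving():
    """One beat at dt = 0.01 vs 0.005 ms: APD90 agrees within 0.5 ms."""
    apds = {}
    for dt in (0.01, 0.005):
        m = CoupledModel(EpParams().for_cell_type("EPI"), MmParams(),
                         dt=dt)
        rec = m.run_interval(initial_y("EPI"), 1000.0, stimulate=True)
        apds[dt] = apd(rec[:, c.R_T], rec[:, c.R_V])
    assert abs(apds[0.01] - apds[0.005]) < 0.5


def test_fixed_step_matches_adaptive_stiff_reference():
    """One beat by the fixed-step scheme vs an adaptive stiff solver:
    peak cytosolic Ca agrees within 1%."""
    from scipy.integrate import solve_ivp

    m = CoupledModel(EpParams().for_cell_type("EPI"), MmParams(),
                     dt=0.005)
    rec = m.run_interval(initial_y("EPI"), 1000.0, stimulate=True)
    peak_fixed = rec[:, c.R_CAI].max()

    def rhs(t, y):
        dy, _ = m.rhs(y, i_stim=(-80.0 if t < 0.5 else 0.0))
        return dy

    sol = solve_ivp(rhs, (0.0, 1000.0), initial_y("EPI"),
                    method="LSODA", rtol=1e-8, atol=1e-10, max_step=0.5,
                    t_eval=np.arange(0.0, 1000.0, 1.0))
    assert sol.success
    peak_ref = sol.y[c.Y_CAI].max()
    assert peak_fixed == pytest.approx(peak_ref, rel=0.01)


def test_pace_first_beat_deterministic():
    t1 = pace("CONTROL", "EPI", 1000.0, n_beats=1, min_beats=1,
              record_last=1, dt=0.02)
    t2 = pace("CONTROL", "EPI", 1000.0, n_beats=2, min_beats=2,
              record_last=2, dt=0.02)
    n = len(t1.data)
    assert np.array_equal(t1.data[:, c.R_V], t2.data[:n, c.R_V])


def test_pace_validates_cycle_length():
    with pytest.raises(ValueError):
        pace("CONTROL", "EPI", 100.0, n_beats=1)


# --------------------------------------------- steady-state phenotypes
CELLS = ("ENDO", "MCELL", "EPI")


@pytest.mark.parametrize("cell", CELLS)
def test_hfpef_diastolic_up_systolic_down(steady, cell):
    """Diastolic [Ca]i is elevated and peak systolic [Ca]i reduced in
    HFpEF for every transmural cell type at 1 Hz."""
    bc = biomarkers_from_trace(steady("CONTROL", cell)[0])
    bh = biomarkers_from_trace(steady("HFPEF", cell)[0])
    assert bh.dia_cai > bc.dia_cai
    assert bh.peak_cai < bc.peak_cai


@pytest.mark.parametrize("cell", CELLS)
def test_hfpef_incomplete_relaxation(steady, cell):
    """HFpEF keeps a residual end-diastolic active force well above the
    control cell's fully relaxed level."""
    bc = biomarkers_from_trace(steady("CONTROL", cell)[0])
    bh = biomarkers_from_trace(steady("HFPEF", cell)[0])
    assert bh.resting_tension > 3.0 * bc.resting_tension


def test_hfpef_sr_content_sodium_potassium_shifts(steady):
    tc, _ = steady("CONTROL", "EPI")
    th, _ = steady("HFPEF", "EPI")
    bc = biomarkers_from_trace(tc)
    bh = biomarkers_from_trace(th)
    assert bh.sr_content < bc.sr_content
    assert th["nai"][-1] > tc["nai"][-1]
    assert th["ki"][-1] < tc["ki"][-1]


@pytest.mark.parametrize("variant", ["CONTROL", "HFPEF"])
def test_transmural_apd_ordering(steady, variant):
    """APD90 ordering MCELL > ENDO > EPI holds in control and HFpEF."""
    apds = {cell: biomarkers_from_trace(steady(variant, cell)[0]).apd90
            for cell in CELLS}
    assert apds["MCELL"] > apds["ENDO"] > apds["EPI"]


# ---------------------------------------------------------------- traces
def test_traceset_roundtrips(tmp_path):
    tr = pace("CONTROL", "EPI", 1000.0, n_beats=1, min_beats=1,
              record_last=1, dt=0.02)
    csv = tmp_path / "t.csv"
    tr.to_csv(csv)
    back = TraceSet.from_csv(csv)
    np.testing.assert_allclose(back.data, tr.data, rtol=1e-15)
    assert back.metadata["cell_type"] == "EPI"
    h5 = tmp_path / "t.h5"
    tr.to_hdf5(h5)
    back = TraceSet.from_hdf5(h5)
    np.testing.assert_array_equal(back.data, tr.data)
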