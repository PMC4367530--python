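"""Electrophysiology layer: reversal potentials, rate evaluation,
state validation, conservation properties."""

import numpy as np
import pytest

import cardioem.constants as c
from cardioem import _kernels as k
from cardioem.coupled import CoupledModel
from cardioem.ep import (EpState, InvalidStateError, ConfigurationError,
                         ep_rates, initial_state)
from cardioem.params import EpParams, MmParams
from cardioem.state import initial_y


def test_potassium_reversal_matches_nernst():
    # closed-form oracle: E_K = (RT/F) ln([K]o/[K]i)
    ep = EpParams()
    ek = ep.rgas * ep.temp / ep.frdy * np.log(5.4 / 145.0)
    assert ek == pytest.approx(-87.8, abs=0.15)
    # the model uses the same expression: at V = E_K the IK1 driving
    # force vanishes, so dV contributions from IK1 change sign there
    st = initial_state("ENDO")
    st.ki = 145.0
    m = CoupledModel(ep.for_cell_type("ENDO"), MmParams(), dt=0.01)
    y = st.to_array()
    y[c.Y_V] = ek
    _, cur = m.rhs(y)
    assert abs(cur[c.CUR_INDEX["ik1"]]) < 1e-10


def test_initial_state_rests_near_minus_88mV():
    # quiescent integration to equilibrium stays within 2 mV of -88
    m = CoupledModel(EpParams().for_cell_type("ENDO"), MmParams(),
                     dt=0.02)
    y = initial_y("ENDO")
    rec = m.run_interval(y, 2000.0, stimulate=False)
    assert rec[-1, c.R_V] == pytest.approx(-88.0, abs=2.0)


def test_initial_state_unknown_cell_type():
    with pytest.raises(ConfigurationError):
        initial_state("PURKINJE")


def test_all_gates_within_unit_interval():
    st = initial_state("EPI")
    for name in ("m", "hf", "hs", "j", "d", "ff", "xk1", "nca"):
        assert 0.0 <= getattr(st, name) <= 1.0


def test_ep_rates_excludes_cytosolic_calcium():
    rates, cur = ep_rates(initial_state("ENDO"), EpParams(), 0.0)
    assert "cai" not in rates
    assert "v" in rates and np.isfinite(rates["v"])
    assert np.isfinite(cur.jup) and np.isfinite(cur.jrel)


def test_invalid_state_error_names_offending_entry():
    st = initial_state("ENDO")
    st.cansr = np.nan
    with pytest.raises(InvalidStateError, match="cansr"):
        ep_rates(st, EpParams())


@pytest.mark.parametrize("v_test", [-120.0, -87.0, -40.0, 0.0, 40.0])
def test_gate_rates_never_leave_unit_interval(v_test):
    """dg/dt = (g_inf - g)/tau with g_inf in [0,1] can never push a
    gate at the boundary outside [0,1]."""
    m = CoupledModel(EpParams().for_cell_type("EPI"), MmParams(),
                     dt=0.01)
    for boundary, sign in ((0.0, 1.0), (1.0, -1.0)):
        y = initial_y("EPI")
        y[c.Y_V] = v_test
        for g in c.RL_GATES:
            y[g] = boundary
        dy, _ = m.rhs(y)
        for g in c.RL_GATES:
            assert sign * dy[g] >= -1e-12


def test_membrane_rate_equals_negative_current_sum():
    """Space-clamped dV/dt = -(sum of ionic currents + I_stim) to
    machine precision."""
    m = CoupledModel(EpParams().for_cell_type("MCELL"), MmParams(),
                     dt=0.01)
    y = initial_y("MCELL")
    y[c.Y_V] = -30.0
    for istim in (0.0, -80.0):
        dy, cur = m.rhs(y, i_stim=istim)
        gx = c.CUR_INDEX
        total = sum(cur[gx[nm]] for nm in (
            "ina", "inal", "ito", "ical", "icana", "icak", "ikr", "iks",
            "ik1", "inaca_i", "inaca_ss", "inak", "inab", "ikb", "ipca",
            "icab"))
        assert dy[c.Y_V] == pytest.approx(-(total + istim), abs=1e-12)


def test_steady_state_end_diastolic_rates_are_small(steady):
    tr, y = steady("CONTROL", "EPI")
    m = CoupledModel(EpParams().for_cell_type("EPI"), MmParams(),
                     dt=0.02)
    dy, _ = m.rhs(y)
    assert abs(dy[c.Y_V]) < 1e-3


def test_steady_state_charge_concentration_consistency(steady):
    """Over one paced beat at steady state each slow concentration
    returns to its start-of-beat value within 0.1%."""
    tr, _ = steady("CONTROL", "EPI")
    for col in (c.R_NAI, c.R_KI, c.R_CANSR):
        start, end = tr.data[0, col], tr.data[-1, col]
        assert abs(end - start) / start < 1e-3


@pytest.mark.parametrize("zeroed", ["gkr", "gncx", "gto"])
def test_current_removal_never_produces_nan(zeroed):
    ep = EpParams().for_cell_type("ENDO")
    setattr(ep, zeroed, 0.0)
    m = CoupledModel(ep, MmParams(), dt=0.02)
    y = initial_y("ENDO")
    for _ in range(10):
        m.run_interval(y, 1000.0, stimulate=True)   # raises on non-finite
    assert np.isfinite(y).all()
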