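"""Myofilament layer: passive elements, crossbridge conservation,
troponin flux sign, steady force-pCa behaviour."""

import numpy as np
import pytest

import cardioem.constants as c
from cardioem import _kernels as k
from cardioem.myofilament import (ConvergenceError, DomainError, MmState,
                                  mm_rates, passive_force, steady_fpca)
from cardioem.params import EpParams, MmParams, pack_params
from cardioem.remodeling import build_variant


def test_titin_vanishes_at_resting_length():
    mm = MmParams()
    assert passive_force(mm.slrest, mm).titin == 0.0


def test_collagen_engages_only_above_threshold():
    mm = MmParams()
    assert passive_force(2.0, mm).collagen == 0.0
    assert passive_force(2.3, mm).collagen > 0.0


def test_titin_monotone_above_rest():
    mm = MmParams()
    sls = np.linspace(mm.slrest, 2.2, 20)
    vals = [passive_force(s, mm).titin for s in sls]
    assert np.all(np.diff(vals) > 0)


@pytest.mark.parametrize("sl", [1.6, 1.85, 2.0, 2.2, 2.35])
def test_hfpef_titin_exactly_doubles_control(sl):
    # PCon_titin x2.00 scales the titin term linearly at every SL
    ctrl = MmParams()
    _, hf, _ = build_variant("HFPEF")
    assert passive_force(sl, hf).titin == pytest.approx(
        2.0 * passive_force(sl, ctrl).titin, rel=1e-12, abs=1e-15)


def test_passive_force_domain_error():
    with pytest.raises(DomainError):
        passive_force(1.0, MmParams())


def test_occupancy_conservation_under_integration():
    """N + P + XBprer + XBpostr stays exactly 1 (P is the algebraic
    closure) and all occupancies stay non-negative over a clamped-Ca
    twitch."""
    prm = pack_params(EpParams(), MmParams())
    y = MmState().to_array()
    for i in range(20000):
        cai_um = 0.1 if i < 1000 else 1.0     # diastole then activation
        k.mm_step_clamped(y, prm, cai_um, 0.01, 1)
    st = MmState.from_array(y)
    assert st.n >= 0 and st.xbprer >= 0 and st.xbpostr >= 0
    assert st.p >= -1e-12
    assert st.n + st.p + st.xbprer + st.xbpostr == pytest.approx(1.0,
                                                                abs=1e-12)


def test_occupancy_rate_sum_is_zero():
    st = MmState(n=0.7, xbprer=0.1, xbpostr=0.05)
    rates, _, _, _ = mm_rates(st, 5e-4, MmParams())
    dp = -(rates["n"] + rates["xbprer"] + rates["xbpostr"])
    # dP follows from closure; total occupancy derivative vanishes to
    # rounding
    assert abs(rates["n"] + dp + rates["xbprer"]
               + rates["xbpostr"]) < 1e-12


def test_no_activation_limit_force_vanishes():
    # 10 s at 10 nM Ca: active force collapses below 1e-3 of the
    # saturating (pCa 4) force
    mm = MmParams()
    prm = pack_params(EpParams(), mm)
    y = MmState(sl=2.2).to_array()
    f_low, _, _ = k.mm_relax_clamped(y, prm, 1e-2, 0.01, 10000.0, 1, 1e-9)
    y = MmState(sl=2.2).to_array()
    f_max, _, _ = k.mm_relax_clamped(y, prm, 100.0, 0.01, 10000.0, 1,
                                     1e-9)
    assert f_low < 1e-3 * f_max


def test_troponin_flux_sign_on_calcium_step():
    """Stepping Ca from diastolic to systolic gives a positive binding
    transient that decays back toward zero."""
    mm = MmParams()
    prm = pack_params(EpParams(), mm)
    y = MmState().to_array()
    k.mm_relax_clamped(y, prm, 0.1, 0.01, 5000.0, 1, 1e-9)
    jt = []
    for _ in range(40000):
        _, _, j = k.mm_step_clamped(y, prm, 1.0, 0.01, 1)
        jt.append(j)
    jt = np.array(jt)
    assert jt[0] > 0
    assert abs(jt[-1]) < 0.02 * jt.max()


def test_mm_rates_isometric_freezes_sarcomere_length():
    st = MmState(sl=2.2, vsl=0.1)
    rates, _, _, _ = mm_rates(st, 5e-4, MmParams(), mode="isometric")
    assert rates["sl"] == 0.0 and rates["vsl"] == 0.0


def test_mm_rates_rejects_bad_inputs():
    with pytest.raises(DomainError):
        mm_rates(MmState(), -1.0, MmParams())
    with pytest.raises(ConvergenceError):
        mm_rates(MmState(n=2.5), 5e-4, MmParams())


@pytest.fixture(scope="module")
def fpca_curves():
    # dense sampling across the (steep, cooperative) transition
    grid = [4.0, 4.5, 5.0, 5.25, 5.5, 5.6, 5.65, 5.7, 5.75, 5.8, 5.85,
            5.9, 5.95, 6.0, 6.1, 6.25, 6.5, 7.0, 8.0]
    ctrl = steady_fpca(grid, 2.2, MmParams())
    _, hf_mm, _ = build_variant("HFPEF")
    hf = steady_fpca(grid, 2.2, hf_mm)
    return ctrl, hf


def test_fpca_monotone_and_bounded(fpca_curves):
    ctrl, _ = fpca_curves
    totals = [p.total for p in ctrl]
    assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))
    assert all(p.total >= p.passive - 1e-12 for p in ctrl)


def test_fpca_no_activation_at_pca8(fpca_curves):
    ctrl, _ = fpca_curves
    top = max(p.active for p in ctrl)
    assert ctrl[-1].active < 1e-2 * top


def test_fpca_hill_coefficient_above_one(fpca_curves):
    """The active F-pCa relation is sigmoidal: a Hill fit returns a
    coefficient > 1 (cooperative activation)."""
    ctrl, _ = fpca_curves
    pca = np.array([p.pca for p in ctrl])
    act = np.array([p.active for p in ctrl])
    act = act / act.max()
    mid = (act > 0.02) & (act < 0.98)
    logit = np.log(act[mid] / (1 - act[mid]))
    # Hill: logit = n ln10 (pca50 - pca)
    slope = np.polyfit(pca[mid], logit, 1)[0]
    n_hill = -slope / np.log(10.0)
    assert n_hill > 1.0


def test_fpca_hfpef_exceeds_control(fpca_curves):
    ctrl, hf = fpca_curves
    for pc, ph in zip(ctrl, hf):
        assert ph.passive > pc.passive
        assert ph.total > pc.total


def test_unloaded_relaxation_settles_at_preload_length():
    """With no Ca activation the unloaded sarcomere settles where the
    passive force balances the preload, and stays there."""
    mm = MmParams()
    prm = pack_params(EpParams(), mm)
    y = MmState(sl=1.7).to_array()
    for _ in range(200000):
        k.mm_step_clamped(y, prm, 1e-2, 0.01, 0)
    sl_rest = y[c.Y_SL]
    assert sl_rest == pytest.approx(mm.slset, abs=0.02)
    for _ in range(50000):
        k.mm_step_clamped(y, prm, 1e-2, 0.01, 0)
    assert y[c.Y_SL] == pytest.approx(sl_rest, abs=1e-4)
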