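"""Protocols: APD measurement, biomarker arithmetic, PRC identity."""

import numpy as np
import pytest

from cardioem.protocols import (Biomarkers, MeasurementError, apd,
                                relative_change, run_prc)


def _biom(**kw):
    base = dict(apd90=200.0, dia_cai=1e-4, peak_cai=5e-4,
                cat_amplitude=4e-4, sr_content=1.8, resting_tension=0.01,
                peak_tension=0.5, sl_shortening=0.1, sr_leak=0.5)
    base.update(kw)
    return Biomarkers(**base)


def test_apd_on_synthetic_triangle():
    """Instant rise to 0 mV then linear fall to -90 mV over 300 ms:
    90% repolarisation sits at 270 ms by plane geometry."""
    t = np.arange(0.0, 401.0)
    v = np.full_like(t, -90.0)
    fall = (t >= 1) & (t <= 301)
    v[fall] = 0.0 - (t[fall] - 1) * (90.0 / 300.0)
    assert apd(t, v) == pytest.approx(270.0, abs=1.0)


def test_apd_constant_trace_raises():
    t = np.arange(100.0)
    with pytest.raises(MeasurementError):
        apd(t, np.full_like(t, -85.0))


def test_apd_unrepolarised_window_raises():
    t = np.arange(0.0, 50.0)
    v = np.where(t < 2, -85.0, 10.0)
    with pytest.raises(MeasurementError):
        apd(t, v)


def test_relative_change_identity_and_doubling():
    b = _biom()
    assert all(v == 0.0 for v in relative_change(b, b).values())
    doubled = _biom(**{k: 2 * v for k, v in b.as_dict().items()})
    assert all(v == pytest.approx(100.0)
               for v in relative_change(doubled, b).values())


def test_relative_change_marks_zero_reference_undefined():
    ref = _biom(resting_tension=0.0)
    out = relative_change(_biom(), ref)
    assert out["resting_tension"] is None
    assert out["apd90"] == 0.0


def test_biomarker_consistency_on_steady_trace(steady):
    from cardioem.protocols import biomarkers_from_trace

    b = biomarkers_from_trace(steady("CONTROL", "ENDO")[0])
    assert b.peak_cai >= b.dia_cai
    assert b.cat_amplitude == pytest.approx(b.peak_cai - b.dia_cai)
    assert b.resting_tension >= 0 and b.peak_tension >= 0
    assert 0 <= b.sl_shortening < 1


def test_prc_control_vs_control_is_exactly_zero():
    """The protocol is deterministic: control against itself gives a
    zero percent change in every defined biomarker."""
    res = run_prc("CONTROL", "EPI", 1.0, rest_intervals=(1.0,),
                  n_condition=5, dt=0.02)
    for rest in res.rest_intervals:
        for name, val in res.percent[rest].items():
            if val is not None:
                assert val == 0.0


def test_prc_reports_all_intervals(prc_results):
    res = prc_results[1.0]
    assert res.rest_intervals == (1.0, 2.0, 3.0, 5.0, 10.0)
    assert set(res.test) == set(res.control) == set(res.rest_intervals)


def test_prc_control_post_rest_decay(prc_results):
    """Human-type myocardium shows post-rest *decay*: with no Ca2+
    entry during rest the SR slowly drains through the leak, so the
    control post-rest systolic tension falls monotonically with the
    rest interval (and the SR content tracks it)."""
    ctrl = prc_results[1.0].control
    rests = (1.0, 2.0, 3.0, 5.0, 10.0)
    peaks = [ctrl[r].peak_tension for r in rests]
    srs = [ctrl[r].sr_content for r in rests]
    assert all(b < a for a, b in zip(peaks, peaks[1:]))
    assert all(b < a for a, b in zip(srs, srs[1:]))


def test_ncx_sweep_single_scale():
    from cardioem.protocols import ncx_sweep

    out = ncx_sweep((0.70,), "EPI", n_beats=2, dt=0.02)
    assert len(out) == 1
    assert out[0].metadata["ncx_scale"] == 0.70
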