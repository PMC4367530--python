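"""Experimental protocols and biomarker extraction.

Steady pacing with biomarker readout, the post-rest contraction (PRC)
protocol probing sarcoplasmic-reticulum Ca2+ content/release/leak, the
Na/Ca-exchanger sensitivity sweep, and the relative-to-control
comparison arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np

from . import constants as c
from .coupled import TraceSet, pace
from .remodeling import as_model


class MeasurementError(ValueError):
    pass


def apd(t: np.ndarray, v: np.ndarray, fraction: float = 0.9) -> float:
    """Action potential duration at ``fraction`` repolarisation (ms).

    Measured from the instant of maximum upstroke velocity to the
    crossing of ``V_peak - fraction * (V_peak - V_diastolic)``, with the
    pre-stimulus sample as the diastolic reference and linear
    interpolation at the threshold crossing.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if len(v) < 3:
        raise MeasurementError("trace too short for APD measurement")
    dv = np.diff(v) / np.diff(t)
    iup = int(np.argmax(dv))
    v_dia = v[0]
    ipk = iup + int(np.argmax(v[iup:]))
    v_pk = v[ipk]
    if v_pk - v_dia < 5.0:
        raise MeasurementError("no action potential found in trace")
    thresh = v_pk - fraction * (v_pk - v_dia)
    below = np.nonzero(v[ipk:] <= thresh)[0]
    if len(below) == 0:
        raise MeasurementError(
            f"repolarisation to {fraction:.0%} not reached in window")
    j = ipk + below[0]
    # linear interpolation between samples j-1 and j
    t_cross = t[j - 1] + (t[j] - t[j - 1]) * \
        (v[j - 1] - thresh) / (v[j - 1] - v[j])
    t_up = t[iup + 1]
    return float(t_cross - t_up)


@dataclass
class Biomarkers:
    """Per-beat cellular biomarkers (concentrations in mM, forces
    normalised, durations in ms)."""

    apd90: float
    dia_cai: float
    peak_cai: float
    cat_amplitude: float
    sr_content: float
    resting_tension: float      # residual active (crossbridge) force at
                                # the diastolic point; in an unloaded
                                # cell the total force is pinned at the
                                # preload and carries no information
    peak_tension: float
    sl_shortening: float
    sr_leak: float          # per-beat integral of the SR leak flux (mM)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


# volume weights for the SR content biomarker
from .params import EpParams as _EpParams
_VNSR = _EpParams.vnsr
_VJSR = _EpParams.vjsr


def biomarkers_from_trace(trace, beat_start: Optional[float] = None,
                          ep=None) -> Biomarkers:
    """Extract the biomarker set from (the last beat of) a trace.

    The diastolic measurement point is the final sample, i.e. the value
    immediately before the next stimulus; SR content is the
    volume-weighted mean of the network and junctional compartments.
    When the trace carries several beats, the final full cycle is used
    (per-beat quantities such as the SR-leak integral refer to one
    beat).
    """
    if isinstance(trace, TraceSet):
        data = trace.data
        if beat_start is None and "cl" in trace.metadata:
            beat_start = data[-1, c.R_T] - float(trace.metadata["cl"])
    else:
        data = np.asarray(trace)
    if beat_start is not None:
        data = data[data[:, c.R_T] >= beat_start - 1e-9]
    t = data[:, c.R_T]
    vnsr = ep.vnsr if ep is not None else _VNSR
    vjsr = ep.vjsr if ep is not None else _VJSR
    try:
        apd90 = apd(t, data[:, c.R_V])
    except MeasurementError:
        apd90 = np.nan
    cai = data[:, c.R_CAI]
    dia = cai[-1]
    peak = cai.max()
    sr = (vnsr * data[-1, c.R_CANSR] + vjsr * data[-1, c.R_CAJSR]) \
        / (vnsr + vjsr)
    sl = data[:, c.R_SL]
    leak = float(np.trapezoid(data[:, c.R_JLEAK], t))
    return Biomarkers(
        apd90=float(apd90),
        dia_cai=float(dia),
        peak_cai=float(peak),
        cat_amplitude=float(peak - dia),
        sr_content=float(sr),
        resting_tension=float(data[-1, c.R_FACT]),
        peak_tension=float(data[:, c.R_FACT].max()),
        sl_shortening=float((sl.max() - sl.min()) / sl.max()),
        sr_leak=leak,
    )


UNDEFINED = None


def relative_change(test: Biomarkers, ref: Biomarkers) -> dict:
    """Percent change of each biomarker, 100 (test - ref)/ref; entries
    with a zero reference are marked ``None`` (undefined ratio)."""
    out = {}
    for name, tv in test.as_dict().items():
        rv = getattr(ref, name)
        if rv == 0 or not np.isfinite(rv):
            out[name] = UNDEFINED
        else:
            out[name] = 100.0 * (tv - rv) / rv
    return out


@dataclass
class PrcResult:
    """Post-rest contraction outcome: per rest interval, biomarkers for
    the test variant and control plus percent changes."""

    rate_hz: float
    rest_intervals: tuple
    test: dict = field(default_factory=dict)      # interval -> Biomarkers
    control: dict = field(default_factory=dict)
    percent: dict = field(default_factory=dict)   # interval -> dict

    def series(self, biomarker: str) -> np.ndarray:
        return np.array([self.percent[r][biomarker]
                         for r in self.rest_intervals], float)


REST_INTERVALS = (1.0, 2.0, 3.0, 5.0, 10.0)


def _prc_biomarkers(rest_rec, beat_rec, ep) -> Biomarkers:
    """Biomarkers for one post-rest contraction.

    Diastolic quantities (Ca level, SR content, resting tension) are
    read at the end of the rest interval, immediately before the
    post-rest stimulus; systolic quantities and the per-beat SR-leak
    integral come from the single post-rest beat.
    """
    t = beat_rec[:, c.R_T]
    try:
        apd90 = apd(t, beat_rec[:, c.R_V])
    except MeasurementError:
        apd90 = np.nan
    dia = rest_rec[-1, c.R_CAI]
    peak = beat_rec[:, c.R_CAI].max()
    sr = (ep.vnsr * rest_rec[-1, c.R_CANSR]
          + ep.vjsr * rest_rec[-1, c.R_CAJSR]) / (ep.vnsr + ep.vjsr)
    sl = beat_rec[:, c.R_SL]
    return Biomarkers(
        apd90=float(apd90),
        dia_cai=float(dia),
        peak_cai=float(peak),
        cat_amplitude=float(peak - dia),
        sr_content=float(sr),
        resting_tension=float(rest_rec[-1, c.R_FACT]),
        peak_tension=float(beat_rec[:, c.R_FACT].max()),
        sl_shortening=float((sl.max() - sl.min()) / sl.max()),
        sr_leak=float(np.trapezoid(beat_rec[:, c.R_JLEAK], t)),
    )


def _prc_one(variant, cell_type, cl, rest_intervals, n_condition, dt,
             condition_cl=None):
    """Condition to steady pacing, then measure one post-rest beat per
    rest interval.  Returns {interval: Biomarkers}."""
    model = as_model(variant, cell_type, dt)
    # fixed-duration conditioning (no early exit), as in the protocol
    _, y = pace(model, cell_type, condition_cl or cl,
                n_beats=n_condition, record_last=1, dt=dt,
                min_beats=n_condition, return_state=True)
    out = {}
    for rest in rest_intervals:
        yr = y.copy()
        rest_rec = model.run_interval(yr, 1000.0 * rest, stimulate=False)
        beat_rec = model.run_interval(yr, cl, stimulate=True)
        out[rest] = _prc_biomarkers(rest_rec, beat_rec, model.ep)
    return out


def run_prc(variant, cell_type: str, rate_hz: float = 1.0,
            rest_intervals: Sequence[float] = REST_INTERVALS,
            n_condition: int = 600, dt: float = 0.01,
            condition_at_test_rate: bool = True) -> PrcResult:
    """Post-rest contraction protocol.

    Condition with ``n_condition`` beats (600 emulates the 10 min at
    1 Hz convention), insert rests of 1-10 s, deliver a single stimulus
    and report the biomarker set on the post-rest beat, together with
    the percent change against CONTROL run under the identical protocol.
    By default conditioning runs at the test rate.
    """
    cl = 1000.0 / rate_hz
    ccl = cl if condition_at_test_rate else 1000.0
    test = _prc_one(variant, cell_type, cl, tuple(rest_intervals),
                    n_condition, dt, ccl)
    ctrl = _prc_one("CONTROL", cell_type, cl, tuple(rest_intervals),
                    n_condition, dt, ccl)
    res = PrcResult(rate_hz, tuple(rest_intervals), test, ctrl)
    for rest in rest_intervals:
        res.percent[rest] = relative_change(test[rest], ctrl[rest])
    res.percent_meta = {"n_condition": n_condition,
                        "reduced_conditioning": n_condition < 600}
    return res


def ncx_sweep(scales: Sequence[float] = (0.70, 1.00, 1.50, 1.75),
              cell_type: str = "EPI", cl: float = 1000.0,
              n_beats: int = 1000, dt: float = 0.01) -> list[TraceSet]:
    """Steady 1 Hz pacing of the HFpEF background with the Na/Ca
    exchanger scaled through ``scales``; one TraceSet per scale."""
    from .remodeling import ncx_scaled_variant
    from .coupled import CoupledModel

    if any(s <= 0 for s in scales):
        raise ValueError("all NCX scales must be > 0")
    out = []
    for s in scales:
        ep, mm, spec = ncx_scaled_variant(s, cell_type)
        model = CoupledModel(ep, mm, dt)
        tr = pace(model, cell_type, cl, n_beats=n_beats, record_last=1,
                  dt=dt)
        tr.metadata["ncx_scale"] = s
        tr.metadata["variant"] = f"HFPEF(NCX x{s:.2f})"
        out.append(tr)
    return out
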