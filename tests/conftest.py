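"""Shared fixtures: expensive steady-state pacing runs are computed once
per session and reused across the unit and acceptance tests.

All heavy cell runs use the 0.02 ms fixed step (the upper end of the
stable range; step-size sensitivity is itself under test) and pace to
convergence with a 400-beat floor, which brings every biomarker within
a few tenths of a percent of its fully pre-paced value.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardioem.coupled import pace
from cardioem.protocols import run_prc

TEST_DT = 0.02
STEADY_MIN_BEATS = 400


@pytest.fixture(scope="session")
def steady():
    """Cache of steady-state pacing runs keyed by (variant, cell, cl).

    Returns a getter ``steady(variant, cell_type, cl=1000)`` yielding
    ``(TraceSet, final_state_vector)``.
    """
    cache = {}

    def get(variant, cell_type, cl=1000.0):
        key = (str(variant), cell_type, cl)
        if key not in cache:
            cache[key] = pace(variant, cell_type, cl, n_beats=1000,
                              min_beats=STEADY_MIN_BEATS, record_last=1,
                              dt=TEST_DT, return_state=True)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def prc_results():
    """HFpEF-vs-control post-rest contraction outcomes at 1 and 2 Hz
    (reduced 300-beat conditioning, flagged in the result metadata)."""
    return {rate: run_prc("HFPEF", "EPI", rate, n_condition=300,
                          dt=TEST_DT) for rate in (1.0, 2.0)}


@pytest.fixture(scope="session")
def ncx_traces():
    """Steady 1 Hz traces of the HFpEF background over the NCX scales."""
    from cardioem.protocols import ncx_sweep

    return ncx_sweep((0.70, 1.00, 1.50, 1.75), "EPI", n_beats=1000,
                     dt=TEST_DT)


@pytest.fixture(scope="session")
def lv_em_results():
    """Coarse-mesh staggered electromechanics runs for all four wall
    thickness presets (shared single-cell gamma tables)."""
    from cardioem.mechanics import run_em, _cell_gamma_tables
    from cardioem.remodeling import variant_spec
    from cardioem.params import MmParams

    spec = variant_spec("HFPEF")
    tables = _cell_gamma_tables(spec, 1000.0, MmParams().slset, TEST_DT,
                                1000, ("ENDO", "EPI", "MCELL"), 300)
    out = {}
    for preset in ("NORMAL", "MILD", "MODERATE", "SEVERE"):
        out[preset] = run_em(preset, "HFPEF", t_end=700.0, dt_mech=10.0,
                             n_theta=12, n_long=6, n_trans=2,
                             gamma_tables=tables)
    return out
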