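"""Coupled electromechanical single cell.

The electrophysiology and myofilament sub-models share one state vector;
the coupling link is the cytosolic Ca2+ balance

    d[Ca]i/dt = beta_Cai * ( -(IpCa + ICab - 2 INaCa,i) Acap/(2 F vmyo)
                             - Jup vnsr/vmyo + Jdiff,Ca vss/vmyo
                             - JTrop/1000 )

where the buffer factor beta_Cai contains only the calmodulin buffer and
the troponin binding flux JTrop (uM/ms) is supplied by the myofilament
model.  The intrinsic troponin buffer of the source electrophysiology
model is removed from this equation to avoid double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from . import constants as c
from . import _kernels as k
from .params import EpParams, MmParams, pack_params, CELL_TYPES
from .tables import build_table
from .state import initial_y


class IntegrationError(RuntimeError):
    pass


def beta_cai(cai: float, cmdn: float, km_cmdn: float) -> float:
    """Calmodulin buffer factor for the cytosolic Ca2+ balance.

    ``beta = 1 / (1 + [CMDN] Km / (Km + [Ca]i)^2)``; lies in (0, 1].
    """
    if cai <= 0 or km_cmdn <= 0 or cmdn < 0:
        raise ValueError("require cai > 0, km_cmdn > 0, cmdn >= 0")
    return 1.0 / (1.0 + cmdn * km_cmdn / (km_cmdn + cai) ** 2)


def d_cai(currents, j_trop: float, cai: float, ep: EpParams) -> float:
    """Cytosolic Ca2+ rate (mM/ms) from the coupling balance.

    ``currents`` provides ipca, icab, inaca_i (uA/uF), jup (mM/ms) and
    jdiff (mM/ms); ``j_trop`` is the troponin binding flux in uM/ms
    (divided by 1000 to bridge into mM/ms).
    """
    b = beta_cai(cai, ep.cmdn, ep.kmcmdn)
    return b * (
        -(currents.ipca + currents.icab - 2.0 * currents.inaca_i)
        * ep.acap / (2.0 * ep.frdy * ep.vmyo)
        - currents.jup * ep.vnsr / ep.vmyo
        + currents.jdiff * ep.vss / ep.vmyo
        - j_trop / 1000.0)


@dataclass
class CoupledState:
    """Full cell state: flat vector plus simulation time (ms)."""

    y: np.ndarray
    t: float = 0.0

    def copy(self) -> "CoupledState":
        return CoupledState(self.y.copy(), self.t)

    @property
    def v(self) -> float:
        return float(self.y[c.Y_V])

    @property
    def cai(self) -> float:
        return float(self.y[c.Y_CAI])

    @property
    def sl(self) -> float:
        return float(self.y[c.Y_SL])


@dataclass
class TraceSet:
    """Uniformly sampled record of one protocol run."""

    data: np.ndarray                      # (n_samples, N_REC)
    metadata: dict = field(default_factory=dict)

    columns = tuple(c.TRACE_COLUMNS)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[:, c.TRACE_COLUMNS.index(name)]

    @property
    def t(self) -> np.ndarray:
        return self["t"]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.data, columns=list(self.columns))

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            for key, val in sorted(self.metadata.items()):
                fh.write(f"# {key}: {val}\n")
            df.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        import pandas as pd

        meta = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].strip().partition(": ")
                meta[key] = _parse_meta(val)
        df = pd.read_csv(path, skiprows=skip,
                         float_precision="round_trip")
        return cls(df.to_numpy(), meta)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("trace", data=self.data)
            ds.attrs["columns"] = ",".join(self.columns)
            for key, val in self.metadata.items():
                fh.attrs[key] = val

    @classmethod
    def from_hdf5(cls, path) -> "TraceSet":
        import h5py

        with h5py.File(path, "r") as fh:
            data = fh["trace"][...]
            meta = {key: fh.attrs[key] for key in fh.attrs}
        return cls(data, dict(meta))


def _parse_meta(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if val in ("True", "False"):
        return val == "True"
    return val


class CoupledModel:
    """Parameter set + lookup table + fixed-step integrator for one cell.

    ``dt`` is the fixed step (ms) the Rush-Larsen table is built for;
    the stimulus convention is -80 uA/uF for 0.5 ms at beat start.
    """

    def __init__(self, ep: EpParams, mm: MmParams, dt: float = 0.01,
                 stim_amp: float = -80.0, stim_dur: float = 0.5):
        if dt > 0.02:
            raise ValueError("fixed-step integration requires dt <= 0.02 ms")
        self.ep = ep
        self.mm = mm
        self.dt = dt
        self.stim_amp = stim_amp
        self.stim_dur = stim_dur
        self.prm = pack_params(ep, mm)
        self.tab = build_table(ep, dt)

    def initial_state(self) -> CoupledState:
        return CoupledState(initial_y(self.ep.celltype), 0.0)

    # ------------------------------------------------------------------
    def run_interval(self, y: np.ndarray, duration: float,
                     stimulate: bool = True, sample_dt: float = 1.0,
                     isometric: bool = False) -> np.ndarray:
        """Integrate ``duration`` ms in place; return the sampled record."""
        n_steps = int(round(duration / self.dt))
        sample_every = max(1, int(round(sample_dt / self.dt)))
        n_samp = n_steps // sample_every + 2
        rec = np.empty((n_samp, c.N_REC))
        amp = self.stim_amp if stimulate else 0.0
        bad = k.run_interval(y, self.prm, self.tab, self.dt, n_steps,
                             amp, self.stim_dur, sample_every, rec,
                             1 if isometric else 0)
        if bad >= 0:
            raise IntegrationError(
                f"membrane potential became non-finite at t={bad * self.dt}"
                " ms")
        n_rows = (n_steps + sample_every - 1) // sample_every + 1
        return rec[:n_rows]

    def step(self, state: CoupledState, dt: Optional[float] = None,
             i_stim: float = 0.0, isometric: bool = False) -> CoupledState:
        """Advance one step (returns a new state; dt defaults to model dt)."""
        if dt is None:
            dt = self.dt
        if abs(dt - self.dt) > 1e-12:
            # table Rush-Larsen factors are dt-specific
            model = CoupledModel(self.ep, self.mm, dt,
                                 self.stim_amp, self.stim_dur)
            return model.step(state, dt, i_stim, isometric)
        out = state.copy()
        dy = np.empty(c.NY)
        cur = np.empty(c.N_CUR)
        ginf = np.empty(c.N_GATES)
        grlf = np.empty(c.N_GATES)
        k.step(out.y, self.prm, self.tab, i_stim, dt,
               1 if isometric else 0, dy, cur, ginf, grlf)
        if not np.isfinite(out.y).all():
            bad = [n for n, i in (("v", c.Y_V),) if not np.isfinite(out.y[i])]
            raise IntegrationError(f"non-finite state after step: {bad}")
        out.t = state.t + dt
        return out

    def rhs(self, y: np.ndarray, i_stim: float = 0.0,
            isometric: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Time derivatives and current/flux vector at state ``y``."""
        dy = np.empty(c.NY)
        cur = np.empty(c.N_CUR)
        ginf = np.empty(c.N_GATES)
        grlf = np.empty(c.N_GATES)
        k.core(y, self.prm, self.tab, i_stim, 1 if isometric else 0,
               dy, cur, ginf, grlf)
        return dy, cur


def pace(variant, cell_type: str, cl: float, n_beats: int = 1000,
         record_last: int = 2, dt: float = 0.01, sample_dt: float = 1.0,
         y0: Optional[np.ndarray] = None, min_beats: int = 200,
         return_state: bool = False):
    """Steady-state pacing protocol.

    ``variant`` is a variant name ("CONTROL", "HFPEF", "HFREF"), a
    ``VariantSpec`` or a prebuilt ``CoupledModel``.  Pacing stops early
    once the beat-to-beat APD90 change is below 0.1 ms and the diastolic
    [Ca2+]i change below 0.5% for three consecutive beats; otherwise a
    ``steady_state`` warning flag is left False in the metadata.

    Returns a :class:`TraceSet` of the last ``record_last`` beats (and
    the final state vector when ``return_state`` is set).
    """
    from .protocols import apd
    from .remodeling import as_model

    if not 250 <= cl <= 2000:
        raise ValueError("cycle length must lie in [250, 2000] ms")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    model = as_model(variant, cell_type, dt)
    y = initial_y(model.ep.celltype) if y0 is None else y0.copy()

    kept: list[np.ndarray] = []
    prev_apd = np.nan
    prev_dia = np.nan
    hits = 0
    steady = False
    beats_run = 0
    for b in range(n_beats):
        rec = model.run_interval(y, cl, stimulate=True, sample_dt=sample_dt)
        beats_run = b + 1
        kept.append(rec)
        if len(kept) > record_last:
            kept.pop(0)
        try:
            a = apd(rec[:, c.R_T], rec[:, c.R_V])
        except ValueError:
            a = np.nan
        dia = rec[-1, c.R_CAI]
        if (np.isfinite(prev_apd) and abs(a - prev_apd) < 0.1
                and abs(dia - prev_dia) / prev_dia < 0.005):
            hits += 1
            if hits >= 3 and b + 1 >= min_beats:
                steady = True
                break
        else:
            hits = 0
        prev_apd, prev_dia = a, dia

    # concatenate kept beats on a global time axis
    parts = []
    for i, rec in enumerate(kept):
        r = rec[:-1].copy() if i < len(kept) - 1 else rec.copy()
        r[:, c.R_T] += (beats_run - len(kept) + i) * cl
        parts.append(r)
    data = np.vstack(parts)
    trace = TraceSet(data, {
        "variant": getattr(variant, "name", str(variant)),
        "cell_type": cell_type,
        "cl": cl,
        "n_beats": beats_run,
        "steady_state": steady,
        "dt": dt,
        "sample_dt": sample_dt,
        "record_last": min(record_last, beats_run),
    })
    if return_state:
        return trace, y
    return trace
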