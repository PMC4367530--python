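"""Run configuration, output writers and fixture generation.

A run is fully described by a :class:`RunConfig`; every algorithm in the
package is deterministic (no random numbers anywhere), so identical
configs produce byte-identical outputs.  Time series are written as CSV
with a commented metadata header (HDF5 optional), field snapshots as
ASCII VTU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


class UsageError(ValueError):
    pass


_PROTOCOLS = ("pace", "prc", "fpca", "ncx-sweep", "cv", "lv-em")


@dataclass
class RunConfig:
    """Serializable description of one reproducible run."""

    protocol: str = "pace"
    variant: str = "CONTROL"
    overrides: dict = field(default_factory=dict)
    cell_type: str = "EPI"
    cl: float = 1000.0
    n_beats: int = 1000
    min_beats: int = 200
    dt: float = 0.01
    rate_hz: float = 1.0
    rest_intervals: tuple = (1.0, 2.0, 3.0, 5.0, 10.0)
    n_condition: int = 600
    ncx_scales: tuple = (0.70, 1.00, 1.50, 1.75)
    pca_grid: tuple = tuple(float(x)
                            for x in np.round(np.arange(4.0, 7.25, 0.25),
                                              2))
    sl: float = 2.2
    # tissue / mesh
    strand_length: float = 20.0
    dx: float = 0.2
    preset: str = "NORMAL"
    n_theta: int = 12
    n_long: int = 6
    n_trans: int = 2
    t_end: float = 700.0
    dt_mech: float = 10.0
    out_dir: str = "."

    def validate(self) -> None:
        from .params import CELL_TYPES
        from .remodeling import VARIANT_NAMES

        if self.protocol not in _PROTOCOLS:
            raise UsageError(
                f"unknown protocol {self.protocol!r}; valid: {_PROTOCOLS}")
        if self.variant not in VARIANT_NAMES + ("CUSTOM",):
            raise UsageError(
                f"unknown variant {self.variant!r}; valid: "
                f"{VARIANT_NAMES + ('CUSTOM',)}")
        if self.cell_type not in CELL_TYPES:
            raise UsageError(
                f"unknown cell type {self.cell_type!r}; valid: "
                f"{CELL_TYPES}")
        if self.dt <= 0 or self.dt > 0.02:
            raise UsageError("dt must lie in (0, 0.02] ms")

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        for key in ("rest_intervals", "ncx_scales", "pca_grid"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def write_vtu(path, points: np.ndarray, tets: np.ndarray,
              point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Minimal ASCII VTU (unstructured grid of tetrahedra) writer."""
    points = np.asarray(points, float)
    tets = np.asarray(tets, int)
    lines = []
    ap = lines.append
    ap('<?xml version="1.0"?>')
    ap('<VTKFile type="UnstructuredGrid" version="0.1" '
       'byte_order="LittleEndian">')
    ap('  <UnstructuredGrid>')
    ap(f'    <Piece NumberOfPoints="{len(points)}" '
       f'NumberOfCells="{len(tets)}">')
    ap('      <Points>')
    ap('        <DataArray type="Float64" NumberOfComponents="3" '
       'format="ascii">')
    for p in points:
        ap(f'          {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}')
    ap('        </DataArray>')
    ap('      </Points>')
    ap('      <Cells>')
    ap('        <DataArray type="Int64" Name="connectivity" '
       'format="ascii">')
    for t in tets:
        ap('          ' + ' '.join(str(i) for i in t))
    ap('        </DataArray>')
    ap('        <DataArray type="Int64" Name="offsets" format="ascii">')
    ap('          ' + ' '.join(str(4 * (i + 1)) for i in range(len(tets))))
    ap('        </DataArray>')
    ap('        <DataArray type="UInt8" Name="types" format="ascii">')
    ap('          ' + ' '.join('10' for _ in range(len(tets))))
    ap('        </DataArray>')
    ap('      </Cells>')
    for tag, datadict, n_items in (("PointData", point_data, len(points)),
                                   ("CellData", cell_data, len(tets))):
        if not datadict:
            continue
        ap(f'      <{tag}>')
        for name, arr in datadict.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            if len(arr) != n_items:
                raise UsageError(
                    f"{tag} array {name!r} has wrong length")
            ap(f'        <DataArray type="Float64" Name="{name}" '
               f'NumberOfComponents="{ncomp}" format="ascii">')
            for row in arr:
                if ncomp == 1:
                    ap(f'          {row:.10g}')
                else:
                    ap('          ' + ' '.join(f'{x:.10g}' for x in row))
            ap('        </DataArray>')
        ap(f'      </{tag}>')
    ap('    </Piece>')
    ap('  </UnstructuredGrid>')
    ap('</VTKFile>')
    Path(path).write_text('\n'.join(lines) + '\n')


def read_vtu_points(path):
    """Read back points/connectivity of a VTU written by write_vtu."""
    import re

    text = Path(path).read_text()
    def block(name_attr):
        m = re.search(name_attr + r'[^>]*>(.*?)</DataArray>', text,
                      re.S)
        return np.fromstring(m.group(1).replace('\n', ' '), sep=' ')
    pts = block(r'<DataArray type="Float64" NumberOfComponents="3"'
                ).reshape(-1, 3)
    conn = block(r'Name="connectivity"[^>]*').astype(int).reshape(-1, 4)
    return pts, conn


# ------------------------------------------------------------- fixtures
def make_fixtures(kind: str, out_dir=".") -> dict:
    """Deterministic small meshes + configs used by the test suite.

    kinds: ``strand`` (20 mm, dx 0.2, 101 nodes), ``slab`` (unit cube
    with transmural depth spanning [0,1]), ``lv-coarse`` (coarse LV at
    each thickness preset).
    """
    from .geometry import strand_mesh, slab_mesh, lv_preset, \
        THICKNESS_PRESETS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    made = {}
    if kind == "strand":
        x = strand_mesh(20.0, 0.2)
        path = out / "strand.csv"
        np.savetxt(path, x, header="x_mm", comments="# ")
        made["strand"] = str(path)
    elif kind == "slab":
        pts, tets, depth = slab_mesh()
        path = out / "slab.vtu"
        write_vtu(path, pts, tets, point_data={"depth": depth})
        made["slab"] = str(path)
    elif kind == "lv-coarse":
        for preset in THICKNESS_PRESETS:
            mesh = lv_preset(preset, n_theta=12, n_long=6, n_trans=2)
            path = out / f"lv_{preset.lower()}.vtu"
            write_vtu(path, mesh.points, mesh.tets,
                      point_data={"depth": mesh.depth})
            made[preset] = str(path)
    else:
        raise UsageError(
            f"unknown fixture kind {kind!r}; valid: strand, slab, "
            "lv-coarse")
    cfg = RunConfig()
    cfg.to_yaml(out / f"{kind}-config.yaml")
    made["config"] = str(out / f"{kind}-config.yaml")
    return made


# ------------------------------------------------------------------ runs
def run(config: RunConfig) -> dict:
    """Execute one configured protocol; writes artifacts under
    ``config.out_dir`` and returns a summary dict."""
    from . import protocols as proto
    from .coupled import pace
    from .remodeling import variant_spec
    from .tissue import measure_cv
    from .mechanics import run_em
    from .myofilament import steady_fpca
    from .params import MmParams

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = variant_spec(config.variant, config.overrides or None)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"protocol": config.protocol,
                     "variant": spec.name,
                     "factors": dict(spec.factors)}

    if config.protocol == "pace":
        tr = pace(spec, config.cell_type, config.cl,
                  n_beats=config.n_beats, dt=config.dt,
                  min_beats=config.min_beats)
        tr.to_csv(out / "trace.csv")
        b = proto.biomarkers_from_trace(tr)
        summary["biomarkers"] = b.as_dict()
        summary["steady_state"] = bool(tr.metadata["steady_state"])
    elif config.protocol == "prc":
        res = proto.run_prc(spec, config.cell_type, config.rate_hz,
                            config.rest_intervals, config.n_condition,
                            config.dt)
        rows = ["rest_s," + ",".join(
            res.percent[res.rest_intervals[0]].keys())]
        for rest in res.rest_intervals:
            pc = res.percent[rest]
            rows.append(f"{rest}," + ",".join(
                "nan" if v is None else f"{v:.6g}" for v in pc.values()))
        (out / "prc_percent.csv").write_text("\n".join(rows) + "\n")
        summary["percent"] = {r: res.percent[r]
                              for r in res.rest_intervals}
    elif config.protocol == "fpca":
        from .remodeling import build_variant

        _, mm, _ = build_variant(config.variant, config.overrides or None)
        pts = steady_fpca(config.pca_grid, config.sl, mm)
        rows = ["pca,total,passive,active"]
        rows += [f"{p.pca},{p.total:.8g},{p.passive:.8g},{p.active:.8g}"
                 for p in pts]
        (out / "fpca.csv").write_text("\n".join(rows) + "\n")
        summary["fpca_points"] = len(pts)
    elif config.protocol == "ncx-sweep":
        traces = proto.ncx_sweep(config.ncx_scales, config.cell_type,
                                 config.cl, config.n_beats, config.dt)
        for tr in traces:
            tag = f"{tr.metadata['ncx_scale']:.2f}".replace(".", "p")
            tr.to_csv(out / f"ncx_{tag}.csv")
        summary["scales"] = list(config.ncx_scales)
    elif config.protocol == "cv":
        cv = measure_cv(config.strand_length, config.dx,
                        variant=config.variant, dt=config.dt
                        if config.dt <= 0.02 else 0.02)
        summary["cv_cm_s"] = cv
    elif config.protocol == "lv-em":
        fields = run_em(config.preset, config.variant,
                        t_end=config.t_end, dt_mech=config.dt_mech,
                        n_theta=config.n_theta, n_long=config.n_long,
                        n_trans=config.n_trans)
        rows = ["t_ms,volume_ml"]
        rows += [f"{t},{v:.8g}" for t, v in zip(fields.times,
                                                fields.volumes)]
        (out / "volumes.csv").write_text("\n".join(rows) + "\n")
        summary["ef_percent"] = fields.ef
        summary["edv_ml"] = fields.edv
        summary["esv_ml"] = fields.esv
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=float) + "\n")
    return summary
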