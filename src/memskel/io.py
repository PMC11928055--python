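"""Run configuration, snapshots and tabular output.

Configs are YAML: a scenario name, parameter overrides keyed by their
symbol names, feature-flag overrides and run settings. Snapshots are
legacy-VTK polydata (points, live triangles, per-node scalars) plus a
tab-separated sidecar with spectrin edge statuses and myosin endpoints,
which together suffice to resume a run of the same scenario.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .params import Params
from .state import SkeletonState, current_triangles

_RUN_KEYS = {"scenario", "params", "flags", "duration", "release_time",
             "n_reps", "base_seed", "record_every", "snapshot_every",
             "outdir"}


@dataclass
class RunConfig:
    scenario: str = "SHEAR"
    params: dict = field(default_factory=dict)     # Table-symbol overrides
    flags: dict = field(default_factory=dict)
    duration: Optional[float] = None
    release_time: Optional[float] = None
    n_reps: int = 1
    base_seed: int = 0
    record_every: float = 0.5
    snapshot_every: Optional[float] = None
    outdir: str = "memskel_out"

    def make_params(self) -> Params:
        return Params(**self.params)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown top-level or parameter keys are rejected by name; parameter
    values go through the full invariant validation.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    valid_params = {f.name for f in dataclasses.fields(Params)}
    bad = set(cfg.params) - valid_params
    if bad:
        raise ValueError(f"unknown parameter keys: {sorted(bad)}")
    from .forces import FeatureFlags
    valid_flags = {f.name for f in dataclasses.fields(FeatureFlags)}
    bad = set(cfg.flags) - valid_flags
    if bad:
        raise ValueError(f"unknown flag keys: {sorted(bad)}")
    cfg.make_params()       # runs validate_params
    return cfg


def dump_manifest(cfg: RunConfig, p: Params, path) -> None:
    """Write the fully resolved configuration next to the outputs."""
    from . import __version__
    doc = {"scenario": cfg.scenario,
           "params": p.to_dict(),
           "flags": cfg.flags,
           "duration": cfg.duration,
           "release_time": cfg.release_time,
           "n_reps": cfg.n_reps,
           "base_seed": cfg.base_seed,
           "record_every": cfg.record_every,
           "software_version": __version__}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def write_observables(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False, float_format="%.10g")


def write_events(events, path) -> None:
    """Tidy event table: time, event type, payload ids."""
    rows = []
    for t, ev in events:
        for eid in ev.unbound:
            rows.append((t, "UNBIND", eid, ""))
        for eid in ev.rebound:
            rows.append((t, "REBIND", eid, ""))
        for ta, tb in ev.myosin_added:
            rows.append((t, "MYOSIN_ADD", ta, tb))
        for reason, life in ev.myosin_removed:
            rows.append((t, f"MYOSIN_REMOVE_{reason}", f"{life:.6g}", ""))
        for old, new in ev.reattached:
            rows.append((t, "MYOSIN_REATTACH", old, new))
    pd.DataFrame(rows, columns=["time", "event", "a", "b"]).to_csv(
        path, sep="\t", index=False)


def write_snapshot(state: SkeletonState, path,
                   f_membrane: Optional[np.ndarray] = None) -> None:
    """Legacy-VTK polydata snapshot with per-node scalar channels."""
    path = Path(path)
    geo = current_triangles(state)
    n = state.n_nodes
    lines = ["# vtk DataFile Version 3.0", "memskel snapshot", "ASCII",
             "DATASET POLYDATA", f"POINTS {n} double"]
    lines += [" ".join(f"{x:.10g}" for x in row) for row in state.pos]
    t = geo.n_triangles
    lines.append(f"POLYGONS {t} {4 * t}")
    lines += ["3 " + " ".join(map(str, tri)) for tri in geo.tri_nodes]
    lines.append(f"POINT_DATA {n}")
    lines.append("SCALARS kind int 1\nLOOKUP_TABLE default")
    lines += [str(int(k)) for k in state.kind]
    lines.append("SCALARS height double 1\nLOOKUP_TABLE default")
    lines += [f"{z:.10g}" for z in state.pos[:, 2]]
    if f_membrane is not None:
        mag = np.linalg.norm(f_membrane, axis=1)
        lines.append("SCALARS f_membrane double 1\nLOOKUP_TABLE default")
        lines += [f"{v:.10g}" for v in mag]
    path.write_text("\n".join(lines) + "\n")
    # sidecar: edge statuses and myosin endpoints
    side = path.with_suffix(".edges.tsv")
    with side.open("w") as fh:
        fh.write("record\ta\tb\textra\n")
        for (i, j), b in zip(state.edges, state.bound):
            fh.write(f"SPECTRIN\t{i}\t{j}\t{'BOUND' if b else 'UNBOUND'}\n")
        for (i, j) in state.conn:
            fh.write(f"CONNECTOR\t{i}\t{j}\t\n")
        for (ta, tb), birth in zip(state.myosin_tris, state.myosin_birth):
            fh.write(f"MYOSIN\t{ta}\t{tb}\t{birth:.10g}\n")


def read_snapshot_points(path) -> np.ndarray:
    """Read back the point block of a snapshot written by this package."""
    lines = Path(path).read_text().splitlines()
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
    n = int(lines[i].split()[1])
    pts = [tuple(map(float, ln.split())) for ln in lines[i + 1:i + 1 + n]]
    return np.asarray(pts)


def load_snapshot(state: SkeletonState, path) -> SkeletonState:
    """Resume: overwrite positions, edge statuses and myosin cables."""
    path = Path(path)
    pts = read_snapshot_points(path)
    if len(pts) != state.n_nodes:
        raise ValueError("snapshot node count does not match the scenario")
    state.pos = pts
    state.prev_pos = pts.copy()
    side = pd.read_csv(path.with_suffix(".edges.tsv"), sep="\t",
                       keep_default_na=False)
    sp = side[side.record == "SPECTRIN"]
    state.bound = (sp.extra == "BOUND").to_numpy()
    my = side[side.record == "MYOSIN"]
    state.myosin_tris = [[int(a), int(b)] for a, b in zip(my.a, my.b)]
    state.myosin_birth = [float(x) for x in my.extra]
    state.topology_dirty = True
    return state
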