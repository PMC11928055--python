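"""The five canonical in-silico experiments.

* ``ISO_EXTENSION`` / ``ISO_COMPRESSION`` -- a flat patch whose peripheral
  linkers are tied to focal adhesions through springs that start shorter
  (extension) or longer (compression) than their rest length, imposing
  isotropic stress for 180 s.
* ``SHEAR`` -- adhesions only at the two ends, offset (+-360, +-1080, -10)
  nm, pre-stretched so the patch extends along one axis and compresses
  along the other; 120 s under load, then the connectors are released and
  the meshwork evolves 120 s more.
* ``SUSPENDED_CELL`` -- the closed spherical meshwork, no connectors,
  360 s, with optional surface-area constraint and volume exclusion.
* ``ADHERED_CELL`` -- the sphere flattened onto the substrate and pinned
  through short pre-stretched adhesion springs, 360 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from . import dynamics as _dyn
from .forces import FeatureFlags
from .geometry import (ISOTROPIC, SHEAR, MeshSpec, attach_connectors,
                       build_adhered_cell, build_patch_mesh,
                       build_sphere_mesh)
from .params import Params
from .state import SkeletonState

SCENARIO_NAMES = ("ISO_EXTENSION", "ISO_COMPRESSION", "SHEAR",
                  "SUSPENDED_CELL", "ADHERED_CELL")


@dataclass
class Scenario:
    """A fully specified, reproducible experiment configuration."""

    name: str
    mesh_spec: MeshSpec
    layout: Optional[str]          # ISOTROPIC | SHEAR | "ADHERED" | None
    d0_C: Optional[float]
    flags: FeatureFlags
    duration: float                # s
    release_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.release_time is not None and not (
                self.release_time < self.duration):
            raise ValueError("release_time must precede the duration")

    def build(self, p: Params) -> SkeletonState:
        """Construct the initial state (mesh + connectors)."""
        if self.mesh_spec.kind == "PATCH":
            st = build_patch_mesh(self.mesh_spec)
            if self.layout is not None:
                attach_connectors(st, self.layout, p, d0_C=self.d0_C,
                                  adhesion_offset_z=self.mesh_spec.adhesion_offset_z)
            return st
        sphere = build_sphere_mesh(self.mesh_spec)
        if self.name == "ADHERED_CELL":
            return build_adhered_cell(sphere, p, self.mesh_spec)
        return sphere


def make_scenario(name: str, p: Params, **flag_overrides) -> Scenario:
    """Return the named experiment with its default feature flags.

    Keyword arguments override individual flags, e.g.
    ``make_scenario("SHEAR", p, myosin=False, rebinding=False)``.
    """
    if name == "ISO_EXTENSION":
        sc = Scenario(name, MeshSpec(kind="PATCH"), ISOTROPIC, p.d0_C2,
                      FeatureFlags(bending=True), duration=180.0)
    elif name == "ISO_COMPRESSION":
        sc = Scenario(name, MeshSpec(kind="PATCH"), ISOTROPIC, p.d0_C1,
                      FeatureFlags(bending=True), duration=180.0)
    elif name == "SHEAR":
        sc = Scenario(name, MeshSpec(kind="PATCH"), SHEAR, p.d0_C3,
                      FeatureFlags(bending=True, unbinding=True,
                                   rebinding=True, myosin=True),
                      duration=240.0, release_time=120.0)
    elif name == "SUSPENDED_CELL":
        sc = Scenario(name, MeshSpec(kind="SPHERE"), None, None,
                      FeatureFlags(bending=True, unbinding=True,
                                   rebinding=True, myosin=True,
                                   area_constraint=True,
                                   volume_exclusion=True),
                      duration=360.0)
    elif name == "ADHERED_CELL":
        sc = Scenario(name, MeshSpec(kind="ADHERED"), "ADHERED", p.d0_C4,
                      FeatureFlags(bending=True, unbinding=True,
                                   rebinding=True, myosin=True,
                                   area_constraint=True,
                                   volume_exclusion=True),
                      duration=360.0)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    if flag_overrides:
        sc = replace(sc, flags=replace(sc.flags, **flag_overrides))
    return sc


def release_from_adhesions(state: SkeletonState) -> SkeletonState:
    """Detach the meshwork: drop connector edges and adhesion nodes."""
    return _dyn.release_connectors(state)


@dataclass
class SimResult:
    seed: int
    state: SkeletonState
    series: pd.DataFrame
    events: list


def run_replicates(scenario: Scenario, p: Params, n_reps: int,
                   base_seed: int, T: Optional[float] = None,
                   record_every: float = 0.5) -> tuple:
    """Run seeded replicates and summarise across them.

    Replicate ``k`` uses seed ``base_seed + k``. Returns
    ``(results, summary)`` where ``summary`` holds the per-record-time
    mean and standard deviation of every numeric observable.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    results: List[SimResult] = []
    for k in range(n_reps):
        seed = base_seed + k
        state, series, events = _dyn.simulate(scenario, p, T=T, seed=seed,
                                              record_every=record_every)
        results.append(SimResult(seed=seed, state=state, series=series,
                                 events=events))
    stacked = pd.concat([r.series for r in results])
    grouped = stacked.groupby("time")
    summary = pd.concat({"mean": grouped.mean(), "sd": grouped.std(ddof=1)},
                        axis=1)
    return results, summary


def end_time_means(results: List[SimResult], columns=("cumulative_rebound",
                                                      "cumulative_unbound",
                                                      "percent_attached",
                                                      "myosin_count")) -> dict:
    """Across-replicate mean / sd / s.e. of end-of-run observables."""
    out = {}
    for col in columns:
        vals = np.array([r.series[col].iloc[-1] for r in results], float)
        n = len(vals)
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        out[col] = {"mean": float(vals.mean()), "sd": sd,
                    "sem": sd / np.sqrt(n) if n > 1 else 0.0, "n": n}
    return out
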