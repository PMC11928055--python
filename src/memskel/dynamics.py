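"""Overdamped forward-Euler dynamics and the per-step simulation loop.

Node velocities are force over drag (``r <- r + dt/zeta * F``); inertia is
neglected. Each step runs a fixed event order so that a given (scenario,
parameters, seed) triple is bit-reproducible:

1. refresh triangle topology/geometry, 2. force balance, 3. Euler move,
4. volume exclusion, 5. spectrin unbinding, 6. spectrin rebinding,
7. myosin topology update (min-length, re-anchoring), 8. stochastic
myosin addition/removal, 9. observable recording.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay

from . import metrics as _metrics
from .forces import FeatureFlags, surface_area, total_force
from .params import Params
from .remodeling import (RemodelingEvents, rebind_spectrin,
                         stochastic_myosin_events, unbind_spectrin,
                         update_myosin_topology)
from .state import ACTIN, ADHESION_FIXED, SkeletonState


class ExclusionRegion:
    """Hard convex region standing in for the incompressible cytoplasm.

    The initial closed surface is scaled by ``(1 - fraction)^(1/3)`` about
    its volumetric centroid, so the excluded volume is ``1 - fraction`` of
    the initial enclosed volume. Membership tests walk a Delaunay
    tessellation of the scaled hull after an inscribed/circumscribed
    radius prescreen.
    """

    def __init__(self, pos: np.ndarray, tri_nodes: np.ndarray,
                 fraction: float = 0.15):
        v0 = _metrics.enclosed_volume(pos, tri_nodes)
        if v0 <= 0:
            raise ValueError("exclusion region needs a positive enclosed volume")
        self.centroid = _metrics.volume_centroid(pos, tri_nodes)
        self.scale = (1.0 - fraction) ** (1.0 / 3.0)
        verts = self.centroid + self.scale * (pos - self.centroid)
        hull = ConvexHull(verts)
        self.volume = float(hull.volume)
        self._A = hull.equations[:, :3]
        self._b = hull.equations[:, 3]
        self.r_out = float(np.linalg.norm(verts[hull.vertices]
                                          - self.centroid, axis=1).max())
        self.r_in = float((-(self._A @ self.centroid + self._b)).min())
        # tessellation of the convex region: point-location in C
        self._tess = Delaunay(verts[hull.vertices])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test (region boundary counts as inside)."""
        r = np.linalg.norm(points - self.centroid, axis=1)
        out = np.zeros(len(points), dtype=bool)
        out[r < self.r_in] = True
        cand = np.flatnonzero((r >= self.r_in) & (r < self.r_out))
        if len(cand):
            out[cand] = self._tess.find_simplex(points[cand]) >= 0
        return out


def euler_step(state: SkeletonState, f_total: np.ndarray, zeta: float,
               dt: float) -> SkeletonState:
    """Move every mobile node by ``dt/zeta * F``; record pre-step positions."""
    if not np.all(np.isfinite(f_total)):
        raise FloatingPointError(
            f"non-finite force at t={state.time:.4f} s")
    state.prev_pos[:] = state.pos
    state.pos += (dt / zeta) * f_total
    idx = state.caches.get("immobile_idx")
    if idx is None:
        idx = np.flatnonzero(~state.mobile)
    state.pos[idx] = state.prev_pos[idx]      # fixed nodes never move
    state.time += dt
    return state


def apply_volume_exclusion(state: SkeletonState,
                           region: Optional[ExclusionRegion]) -> SkeletonState:
    """Reset any ACTIN node that stepped strictly inside the region."""
    if region is None:
        return state
    actin = state.caches.get("actin_idx")
    if actin is None:
        actin = np.flatnonzero(state.kind == ACTIN)
    inside = region.contains(state.pos[actin])
    if inside.any():
        ids = actin[inside]
        state.pos[ids] = state.prev_pos[ids]
    return state


def release_connectors(state: SkeletonState) -> SkeletonState:
    """Delete all connector edges and their fixed adhesion nodes.

    Linker nodes remain in the meshwork and keep evolving. Idempotent; a
    warning is issued when there is nothing to release.
    """
    if len(state.conn) == 0:
        warnings.warn("release requested but no connectors present")
        return state
    adh = np.flatnonzero(state.kind == ADHESION_FIXED)
    keep = int(adh.min()) if len(adh) else state.n_nodes
    state.pos = state.pos[:keep]
    state.prev_pos = state.prev_pos[:keep]
    state.kind = state.kind[:keep]
    state.mobile = state.mobile[:keep]
    state.conn = np.empty((0, 2), dtype=np.int64)
    state.triangles = None
    state.topology_dirty = True
    return state


def _record(state: SkeletonState, p: Params, flags: FeatureFlags,
            A0: Optional[float], e_b: float) -> dict:
    rec = {
        "time": state.time,
        "n_bound": state.n_bound,
        "percent_attached": _metrics.percent_attached(state),
        "cumulative_unbound": state.cumulative_unbound,
        "cumulative_rebound": state.cumulative_rebound,
        "myosin_count": state.myosin_count,
        "median_length": float(np.median(
            state.edge_lengths(np.flatnonzero(state.bound))))
        if state.n_bound else np.nan,
        "bending_energy": e_b,
    }
    actin = state.kind == ACTIN
    z = state.pos[actin, 2]
    rec["height"] = float(z.max() - z.min())
    if state.base.closed:
        rec["volume"] = _metrics.enclosed_volume(state.pos,
                                                 state.base.tri_nodes)
        rec["projected_area"] = _metrics.projected_area(state)
        rec["area"] = surface_area(state.pos, state.base.tri_nodes)
    return rec


def simulate(scenario, p: Params, T: Optional[float] = None,
             seed: Optional[int] = None, record_every: float = 0.5,
             state: Optional[SkeletonState] = None,
             ) -> Tuple[SkeletonState, pd.DataFrame, list]:
    """Run a scenario for ``T`` seconds (scenario duration by default).

    Parameters
    ----------
    scenario
        Object with ``build(p)``, ``flags``, ``duration`` and
        ``release_time`` attributes (see :mod:`memskel.scenarios`).
    T : float, optional
        Simulated duration, s; defaults to ``scenario.duration``.
    seed : int, optional
        Seed of the per-run random stream (defaults to ``p.seed``).
    record_every : float
        Observable recording cadence, s.
    state : SkeletonState, optional
        Resume from this state instead of building the scenario geometry.

    Returns
    -------
    (final state, observable table, event log)
        The event log is a list of ``(time, RemodelingEvents)`` holding
        only non-empty steps.
    """
    flags: FeatureFlags = scenario.flags
    if state is None:
        state = scenario.build(p)
    state.rng = np.random.default_rng(p.seed if seed is None else seed)
    T = float(scenario.duration if T is None else T)
    release_time = scenario.release_time
    n_steps = int(round(T / p.dt))
    record_stride = max(1, int(round(record_every / p.dt)))

    A0 = None
    if flags.area_constraint:
        A0 = surface_area(state.pos, state.base.tri_nodes)
    region = None
    if flags.volume_exclusion:
        region = ExclusionRegion(state.pos, state.base.tri_nodes,
                                 p.volume_exclusion_fraction)

    records: List[dict] = []
    events: list = []
    released = len(state.conn) == 0
    ff = total_force(state, p, flags, A0)
    records.append(_record(state, p, flags, A0, ff.e_b))

    for step in range(1, n_steps + 1):
        if (not released and release_time is not None
                and state.time >= release_time - 0.5 * p.dt):
            release_connectors(state)
            released = True
        ff = total_force(state, p, flags, A0)
        euler_step(state, ff.f_total, p.zeta, p.dt)
        if flags.volume_exclusion:
            apply_volume_exclusion(state, region)
        ev = RemodelingEvents()
        if flags.unbinding:
            ev.merge(unbind_spectrin(state, p.F_th, p.k_s_S, p.d0_S))
        if flags.rebinding:
            ev.merge(rebind_spectrin(state, p.d0_S))
        if flags.myosin:
            ev.merge(update_myosin_topology(state, p.d_min, p.d_max))
            ev.merge(stochastic_myosin_events(state, p.phi_a, p.phi_r,
                                              p.dt, p.d_min, p.d_max))
        if (ev.any_spectrin or ev.myosin_added or ev.myosin_removed
                or ev.reattached):
            events.append((state.time, ev))
        if step % record_stride == 0 or step == n_steps:
            e_b = ff.e_b
            records.append(_record(state, p, flags, A0, e_b))

    series = pd.DataFrame.from_records(records)
    return state, series, events
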