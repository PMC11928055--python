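"""Topology updates: spectrin unbinding/rebinding and myosin turnover.

Spectrin tetramers dissociate when their spring pushes the junctional
complexes apart harder than a threshold force (compression-driven, as
specified by the model: an edge shorter than rest generates an expansive
force ``k_s_S (d0_S - d)``; above ``F_th`` the edge unbinds). An unbound
edge keeps its node pair and rebinds once the pair separation is at least
the resting length, which guarantees the reborn edge starts under zero or
contractile force.

Myosin cables appear stochastically between live-triangle centers whose
separation lies in ``[d_min, d_max]``, are removed stochastically, vanish
when contracted below ``d_min``, and when one of their support triangles
loses a spectrin edge they try to re-anchor to the nearest surviving
triangle within ``d_max`` (else they are removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .state import SkeletonState, current_triangles

MIN_LENGTH = "MIN_LENGTH"
STOCHASTIC = "STOCHASTIC"
STRANDED = "STRANDED"

_MAX_ADDITION_ATTEMPTS = 64


@dataclass
class RemodelingEvents:
    """Per-step event lists (edge ids, triangle pairs, removal reasons)."""

    unbound: List[int] = field(default_factory=list)
    rebound: List[int] = field(default_factory=list)
    myosin_added: List[Tuple[int, int]] = field(default_factory=list)
    myosin_removed: List[Tuple[str, float]] = field(default_factory=list)
    reattached: List[Tuple[int, int]] = field(default_factory=list)

    def merge(self, other: "RemodelingEvents") -> "RemodelingEvents":
        self.unbound += other.unbound
        self.rebound += other.rebound
        self.myosin_added += other.myosin_added
        self.myosin_removed += other.myosin_removed
        self.reattached += other.reattached
        return self

    @property
    def any_spectrin(self) -> bool:
        return bool(self.unbound or self.rebound)


def unbind_spectrin(state: SkeletonState, F_th: float, k_s_S: float,
                    d0_S: float) -> RemodelingEvents:
    """Unbind every bound edge whose expansive force exceeds ``F_th``."""
    ev = RemodelingEvents()
    if not state.bound.any():
        return ev
    d = state.edge_lengths()
    # k (d0 - d) > F_th, i.e. expansive force beyond the threshold
    hits = np.flatnonzero(state.bound & (d < d0_S - F_th / k_s_S))
    if len(hits):
        state.bound[hits] = False
        state.cumulative_unbound += len(hits)
        state.topology_dirty = True
        ev.unbound = hits.tolist()
    return ev


def rebind_spectrin(state: SkeletonState, d0_S: float) -> RemodelingEvents:
    """Rebind unbound edges whose node pair is at least ``d0_S`` apart."""
    ev = RemodelingEvents()
    if state.bound.all():
        return ev
    d = state.edge_lengths()
    hits = np.flatnonzero(~state.bound & (d >= d0_S))
    if len(hits):
        state.bound[hits] = True
        state.cumulative_rebound += len(hits)
        state.topology_dirty = True
        ev.rebound = hits.tolist()
    return ev


def _tri_center(state: SkeletonState, base_tri: int) -> np.ndarray:
    """Center of a base triangle from current node positions (live or not)."""
    return state.pos[state.base.tri_nodes[base_tri]].mean(axis=0)


def update_myosin_topology(state: SkeletonState, d_min: float,
                           d_max: float) -> RemodelingEvents:
    """Min-length removal, then re-anchoring of cables on dead triangles."""
    ev = RemodelingEvents()
    if not state.myosin_tris:
        return ev
    geo = current_triangles(state, geometry=False)
    live_centers = None      # computed lazily, only when a triangle died

    keep_tris, keep_birth = [], []
    for (ta, tb), birth in zip(state.myosin_tris, state.myosin_birth):
        ca, cb = _tri_center(state, ta), _tri_center(state, tb)
        if np.linalg.norm(cb - ca) < d_min:
            life = state.time - birth
            state.myosin_lifetimes.append(life)
            ev.myosin_removed.append((MIN_LENGTH, life))
            continue
        ends = [ta, tb]
        stranded = False
        for side, tid in enumerate(ends):
            if geo.base_to_local[tid] >= 0:
                continue
            lost_center = _tri_center(state, tid)
            if geo.n_triangles == 0:
                stranded = True
                break
            if live_centers is None:
                live_centers = state.pos[
                    state.base.tri_nodes[geo.alive]].mean(axis=1)
            dist = np.linalg.norm(live_centers - lost_center, axis=1)
            other = geo.base_to_local[ends[1 - side]]
            if other >= 0:
                dist[other] = np.inf     # avoid collapsing onto the partner
            j = int(np.argmin(dist))
            if dist[j] <= d_max:
                ev.reattached.append((tid, int(geo.alive[j])))
                ends[side] = int(geo.alive[j])
            else:
                stranded = True
                break
        if stranded:
            life = state.time - birth
            state.myosin_lifetimes.append(life)
            ev.myosin_removed.append((STRANDED, life))
            continue
        keep_tris.append(ends)
        keep_birth.append(birth)
    state.myosin_tris = keep_tris
    state.myosin_birth = keep_birth
    return ev


def stochastic_myosin_events(state: SkeletonState, phi_a: float, phi_r: float,
                             dt: float, d_min: float,
                             d_max: float) -> RemodelingEvents:
    """One-per-step stochastic addition and independent removals.

    Addition fires with probability ``min(phi_a dt, 1)`` (rates are small,
    so multi-addition corrections are negligible); the new cable spans two
    distinct live-triangle centers whose separation lies in
    ``[d_min, d_max]``, drawn by capped rejection sampling. Each existing
    cable is removed independently with probability ``min(phi_r dt, 1)``.
    """
    ev = RemodelingEvents()
    rng = state.rng
    geo = current_triangles(state, geometry=False)
    if phi_a > 0.0:
        if rng.random() < min(phi_a * dt, 1.0) and geo.n_triangles >= 2:
            for _ in range(_MAX_ADDITION_ATTEMPTS):
                i, j = rng.integers(0, geo.n_triangles, size=2)
                if i == j:
                    continue
                d = np.linalg.norm(_tri_center(state, int(geo.alive[j]))
                                   - _tri_center(state, int(geo.alive[i])))
                if d_min <= d <= d_max:
                    ta, tb = int(geo.alive[i]), int(geo.alive[j])
                    state.myosin_tris.append([ta, tb])
                    state.myosin_birth.append(state.time)
                    ev.myosin_added.append((ta, tb))
                    break
    if phi_r > 0.0 and state.myosin_tris:
        u = rng.random(len(state.myosin_tris))
        doomed = u < min(phi_r * dt, 1.0)
        if doomed.any():
            keep_tris, keep_birth = [], []
            for hit, tri, birth in zip(doomed, state.myosin_tris,
                                       state.myosin_birth):
                if hit:
                    life = state.time - birth
                    state.myosin_lifetimes.append(life)
                    ev.myosin_removed.append((STOCHASTIC, life))
                else:
                    keep_tris.append(tri)
                    keep_birth.append(birth)
            state.myosin_tris = keep_tris
            state.myosin_birth = keep_birth
    return ev
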