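"""Mutable simulation state: nodes, edges, and the triangle geometry.

The meshwork is a fixed set of nodes (short F-actin, linker protein
complexes, and immobile focal-adhesion anchors) joined by spectrin edges
that carry a BOUND/UNBOUND status. Unbound edges keep their node pair --
rebinding always targets the previous partner -- but exert no force and
support no triangles. Triangles (used by membrane bending and as myosin
attachment sites) are the triples of ACTIN nodes whose three pairwise
spectrin edges are all bound; they are always a subset of the initial
triangulation because edges never rewire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# node kinds
ACTIN = 0
LINKER = 1
ADHESION_FIXED = 2


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis plumbing (hot path)."""
    out = np.empty_like(a)
    a0, a1, a2 = a[:, 0], a[:, 1], a[:, 2]
    b0, b1, b2 = b[:, 0], b[:, 1], b[:, 2]
    out[:, 0] = a1 * b2 - a2 * b1
    out[:, 1] = a2 * b0 - a0 * b2
    out[:, 2] = a0 * b1 - a1 * b0
    return out


def _scatter_rows(F: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """F[idx] += vals with repeated indices, via bincount (hot path)."""
    idx3 = (3 * idx[:, None] + np.arange(3)).ravel()
    F += np.bincount(idx3, weights=vals.ravel(),
                     minlength=3 * len(F)).reshape(F.shape)


def _flat3(idx: np.ndarray) -> np.ndarray:
    """Flattened xyz scatter indices for a node-id array (precomputable)."""
    return (3 * np.asarray(idx)[:, None] + np.arange(3)).ravel()


def _scatter_flat(F: np.ndarray, idx3: np.ndarray, vals: np.ndarray) -> None:
    """F.ravel()[idx3] += vals.ravel() with repeats, single bincount."""
    F += np.bincount(idx3, weights=vals.ravel(),
                     minlength=3 * len(F)).reshape(F.shape)


@dataclass
class BaseTopology:
    """Immutable connectivity of the initial triangulation.

    ``tri_nodes`` carries the construction-time winding (counter-clockwise
    seen from outside: +z for patches, radially outward for closed meshes),
    which fixes the outward normal of every descendant triangle set.
    """

    tri_nodes: np.ndarray      # (T0, 3) node ids
    tri_edges: np.ndarray      # (T0, 3) spectrin edge ids of each triangle
    pairs: np.ndarray          # (P0, 2) base-triangle ids sharing an edge
    all_actin: np.ndarray      # (T0,) bool: all three corners are ACTIN
    closed: bool = False       # watertight initial surface


@dataclass
class TriangleGeometry:
    """Per-triangle geometry of the currently bound sub-mesh.

    ``alive`` indexes into the base triangulation; ``pair_local`` indexes
    pairs of *live* triangles into the live arrays. Geometry arrays are
    refreshed from node positions with :meth:`update_geometry`.
    """

    alive: np.ndarray            # (T,) base triangle ids
    tri_nodes: np.ndarray        # (T, 3)
    pair_local: np.ndarray       # (P, 2) indices into live arrays
    base_to_local: np.ndarray    # (T0,) local index or -1
    area: np.ndarray = field(default=None)      # (T,)
    center: np.ndarray = field(default=None)    # (T, 3)
    normal: np.ndarray = field(default=None)    # (T, 3) unit, outward
    raw_normal: np.ndarray = field(default=None)  # (T, 3) un-normalised
    mean_area_product: float = 1.0
    # precomputed scatter indices for the force hot path
    tn_cat3: np.ndarray = field(default=None)
    pa3: np.ndarray = field(default=None)
    pb3: np.ndarray = field(default=None)

    @property
    def n_triangles(self) -> int:
        return len(self.alive)

    def update_geometry(self, pos: np.ndarray) -> None:
        """Recompute areas, centers and outward unit normals.

        Raises
        ------
        FloatingPointError
            If a live triangle is degenerate (zero area).
        """
        a = pos[self.tri_nodes[:, 0]]
        b = pos[self.tri_nodes[:, 1]]
        c = pos[self.tri_nodes[:, 2]]
        n = _cross(b - a, c - a)
        nn = np.sqrt(np.einsum("ij,ij->i", n, n))
        if self.n_triangles and nn.min() <= 0.0:
            raise FloatingPointError("degenerate (zero-area) triangle in live mesh")
        self.raw_normal = n
        self.normal = n / nn[:, None]
        self.area = 0.5 * nn
        self.center = (a + b + c) / 3.0
        if len(self.pair_local):
            prod = self.area[self.pair_local[:, 0]] * self.area[self.pair_local[:, 1]]
            self.mean_area_product = float(prod.mean())
        else:
            self.mean_area_product = 1.0


@dataclass
class SkeletonState:
    """Positions, edge bookkeeping, and counters shared by every module."""

    pos: np.ndarray                  # (N, 3) nm
    prev_pos: np.ndarray             # (N, 3) nm, pre-step positions
    kind: np.ndarray                 # (N,) int8
    mobile: np.ndarray               # (N,) bool
    edges: np.ndarray                # (E, 2) spectrin edge node pairs
    bound: np.ndarray                # (E,) bool
    base: BaseTopology
    conn: np.ndarray                 # (C, 2) (linker/actin id, adhesion id)
    conn_d0: float = 0.0             # connector resting length, nm
    time: float = 0.0
    cumulative_unbound: int = 0
    cumulative_rebound: int = 0
    # myosin cables: endpoints are *base* triangle ids (stable across rebuilds)
    myosin_tris: list = field(default_factory=list)    # [ [ta, tb], ... ]
    myosin_birth: list = field(default_factory=list)   # birth times, s
    myosin_lifetimes: list = field(default_factory=list)  # recorded at removal, s
    rng: Optional[np.random.Generator] = None
    triangles: Optional[TriangleGeometry] = None
    membrane: Optional[TriangleGeometry] = None
    topology_dirty: bool = True
    caches: dict = field(default_factory=dict)  # scatter-index caches

    @property
    def n_nodes(self) -> int:
        return len(self.pos)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_bound(self) -> int:
        return int(self.bound.sum())

    @property
    def myosin_count(self) -> int:
        return len(self.myosin_tris)

    def edge_lengths(self, subset: Optional[np.ndarray] = None) -> np.ndarray:
        """Current lengths of spectrin edges (all of them by default)."""
        if subset is None and "e_i" in self.caches:
            d = self.pos[self.caches["e_i"]] - self.pos[self.caches["e_j"]]
            return np.sqrt(np.einsum("ij,ij->i", d, d))
        e = self.edges if subset is None else self.edges[subset]
        return np.linalg.norm(self.pos[e[:, 0]] - self.pos[e[:, 1]], axis=1)

    def copy(self) -> "SkeletonState":
        import copy as _copy

        st = SkeletonState(
            pos=self.pos.copy(), prev_pos=self.prev_pos.copy(),
            kind=self.kind.copy(), mobile=self.mobile.copy(),
            edges=self.edges.copy(), bound=self.bound.copy(),
            base=self.base, conn=self.conn.copy(), conn_d0=self.conn_d0,
            time=self.time,
            cumulative_unbound=self.cumulative_unbound,
            cumulative_rebound=self.cumulative_rebound,
            myosin_tris=[list(m) for m in self.myosin_tris],
            myosin_birth=list(self.myosin_birth),
            myosin_lifetimes=list(self.myosin_lifetimes),
            rng=_copy.deepcopy(self.rng),
            triangles=None, membrane=None, topology_dirty=True,
        )
        return st


def build_base_topology(edges: np.ndarray, tri_nodes: np.ndarray,
                        kind: np.ndarray, closed: bool = False) -> BaseTopology:
    """Assemble the immutable triangulation bookkeeping.

    Parameters
    ----------
    edges : (E, 2) spectrin edge node pairs (any order within a pair).
    tri_nodes : (T0, 3) triangles with outward winding.
    kind : (N,) node kinds.
    """
    ekey = {}
    for eid, (i, j) in enumerate(np.asarray(edges)):
        ekey[(min(i, j), max(i, j))] = eid
    T0 = len(tri_nodes)
    tri_edges = np.empty((T0, 3), dtype=np.int64)
    for t, (i, j, k) in enumerate(np.asarray(tri_nodes)):
        tri_edges[t, 0] = ekey[(min(i, j), max(i, j))]
        tri_edges[t, 1] = ekey[(min(j, k), max(j, k))]
        tri_edges[t, 2] = ekey[(min(i, k), max(i, k))]
    # adjacency: triangles sharing an edge
    edge_tris: dict = {}
    for t in range(T0):
        for eid in tri_edges[t]:
            edge_tris.setdefault(int(eid), []).append(t)
    pairs = sorted(
        tuple(ts) for ts in edge_tris.values() if len(ts) == 2
    )
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    all_actin = np.all(kind[np.asarray(tri_nodes)] == ACTIN, axis=1)
    return BaseTopology(
        tri_nodes=np.asarray(tri_nodes, dtype=np.int64),
        tri_edges=tri_edges, pairs=pairs, all_actin=all_actin, closed=closed,
    )


def rebuild_triangles(state: SkeletonState) -> TriangleGeometry:
    """Re-enumerate live triangles from the current edge statuses.

    A base triangle is live when its three corners are ACTIN and its three
    spectrin edges are BOUND; linker nodes never enter the membrane-force
    triangulation. The live adjacency keeps the pairs whose two triangles
    both survive. Idempotent for an unchanged state.
    """
    base = state.base
    alive_mask = base.all_actin & np.all(state.bound[base.tri_edges], axis=1)
    alive = np.flatnonzero(alive_mask)
    base_to_local = np.full(len(base.tri_nodes), -1, dtype=np.int64)
    base_to_local[alive] = np.arange(len(alive))
    if len(base.pairs):
        pa = alive_mask[base.pairs[:, 0]] & alive_mask[base.pairs[:, 1]]
        pair_local = base_to_local[base.pairs[pa]]
    else:
        pair_local = np.empty((0, 2), dtype=np.int64)
    geo = _finalize_geometry(TriangleGeometry(
        alive=alive,
        tri_nodes=base.tri_nodes[alive],
        pair_local=pair_local,
        base_to_local=base_to_local,
    ))
    geo.update_geometry(state.pos)
    # scatter-index caches for the force hot path
    state.caches = {
        "spectrin_edges": state.edges[state.bound],
    }
    e = state.caches["spectrin_edges"]
    state.caches["sp_i3"] = _flat3(e[:, 0]) if len(e) else np.empty(0, np.int64)
    state.caches["sp_j3"] = _flat3(e[:, 1]) if len(e) else np.empty(0, np.int64)
    c = state.conn
    state.caches["cn_i3"] = _flat3(c[:, 0]) if len(c) else np.empty(0, np.int64)
    state.caches["cn_j3"] = _flat3(c[:, 1]) if len(c) else np.empty(0, np.int64)
    state.caches["e_i"] = np.ascontiguousarray(state.edges[:, 0])
    state.caches["e_j"] = np.ascontiguousarray(state.edges[:, 1])
    state.caches["immobile_idx"] = np.flatnonzero(~state.mobile)
    state.caches["actin_idx"] = np.flatnonzero(state.kind == ACTIN)
    state.triangles = geo
    state.topology_dirty = False
    return geo


def _finalize_geometry(geo: TriangleGeometry) -> TriangleGeometry:
    tn, pl = geo.tri_nodes, geo.pair_local
    geo.tn_cat3 = (_flat3(np.concatenate([tn[:, 0], tn[:, 1], tn[:, 2]]))
                   if len(tn) else np.empty(0, np.int64))
    geo.pa3 = _flat3(pl[:, 0]) if len(pl) else np.empty(0, np.int64)
    geo.pb3 = _flat3(pl[:, 1]) if len(pl) else np.empty(0, np.int64)
    return geo


def membrane_triangles(state: SkeletonState,
                       geometry: bool = True) -> TriangleGeometry:
    """Fixed membrane triangulation used by bending and membrane forces.

    The membrane persists over transiently unbound patches of the
    skeleton, so its triangulation is the full initial one restricted to
    all-ACTIN triangles (linker nodes carry no membrane force); it never
    shrinks when spectrin edges unbind. Myosin, by contrast, attaches
    only to triangles whose three spectrin edges are bound
    (see :func:`rebuild_triangles`).
    """
    if state.membrane is None:
        base = state.base
        mask = base.all_actin
        alive = np.flatnonzero(mask)
        base_to_local = np.full(len(base.tri_nodes), -1, dtype=np.int64)
        base_to_local[alive] = np.arange(len(alive))
        if len(base.pairs):
            pa = mask[base.pairs[:, 0]] & mask[base.pairs[:, 1]]
            pair_local = base_to_local[base.pairs[pa]]
        else:
            pair_local = np.empty((0, 2), dtype=np.int64)
        state.membrane = _finalize_geometry(TriangleGeometry(
            alive=alive, tri_nodes=base.tri_nodes[alive],
            pair_local=pair_local, base_to_local=base_to_local,
        ))
        state.membrane.update_geometry(state.pos)
    elif geometry:
        state.membrane.update_geometry(state.pos)
    return state.membrane


def current_triangles(state: SkeletonState,
                      geometry: bool = True) -> TriangleGeometry:
    """Return cached triangle topology, rebuilding only when dirty.

    With ``geometry=False`` only the topology is guaranteed fresh (the
    fused force kernels recompute areas/normals themselves).
    """
    if state.topology_dirty or state.triangles is None:
        return rebuild_triangles(state)
    if geometry:
        state.triangles.update_geometry(state.pos)
    return state.triangles
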