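"""Forces of the spring-and-cable membrane-skeleton model.

Components:

* Hookean spectrin and connector springs: an edge of length ``d`` and rest
  length ``d0`` pulls its nodes together when stretched and pushes them
  apart when compressed, with magnitude ``k |d - d0|``.
* Discrete membrane bending on the fixed membrane triangulation (the
  membrane persists over transiently unbound skeleton patches):
  ``E_b = k_b * sum_pairs [1 - cos(theta_ab - theta0)] * A_a A_b / <A A>``,
  where the sum runs over adjacent triangle pairs, ``theta_ab`` is the
  angle between outward unit normals and the area-product weight is
  normalised by its mean over the current pairs.
  The force is the exact negative gradient (area weights and the mean
  normalisation included), so it matches a finite difference of the energy.
* A global surface-area constraint ``E_A = (k_A/2) (A - A0)^2 / A0``
  evaluated on the full initial triangulation.
* Tension-only myosin cables between live-triangle centers: tension
  ``k_c_M * d`` along the center-to-center axis, each end split equally
  among that triangle's three actin nodes.

All routines return per-node force arrays shaped like ``pos``; forces on
immobile nodes are computed but never applied by the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as _K
from .params import Params
from .state import (SkeletonState, TriangleGeometry, current_triangles,
                    membrane_triangles)
from .state import _cross, _scatter_flat, _scatter_rows


@dataclass
class FeatureFlags:
    """Which force/remodeling modules a scenario enables."""

    bending: bool = True
    unbinding: bool = False
    rebinding: bool = False
    myosin: bool = False
    area_constraint: bool = False
    volume_exclusion: bool = False


@dataclass
class ForceField:
    """Per-node force components and bookkeeping scalars."""

    f_spring_S: np.ndarray
    f_spring_C: np.ndarray
    f_bend: np.ndarray
    f_area: np.ndarray
    f_myosin: np.ndarray
    e_b: float = 0.0
    area: float = 0.0
    area0: float = 0.0

    @property
    def f_membrane(self) -> np.ndarray:
        return self.f_bend + self.f_area

    @property
    def f_total(self) -> np.ndarray:
        return (self.f_spring_S + self.f_spring_C + self.f_myosin
                + self.f_membrane)


def spring_forces(pos: np.ndarray, edges: np.ndarray, k_s: float, d0: float,
                  out: Optional[np.ndarray] = None) -> np.ndarray:
    """Axial Hookean forces for the given edge subset.

    Raises
    ------
    ValueError
        On a zero-length edge (undefined direction).
    """
    F = np.zeros_like(pos) if out is None else out
    if len(edges) == 0:
        return F
    ri = pos[edges[:, 0]]
    rj = pos[edges[:, 1]]
    dvec = rj - ri
    d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
    if d.min() <= 0.0:
        raise ValueError("zero-length edge: spring direction undefined")
    # F_i = k (d - d0) * (r_j - r_i)/d : contractile when stretched,
    # expansive when compressed
    coef = (k_s * (d - d0) / d)[:, None]
    fij = coef * dvec
    _scatter_rows(F, edges[:, 0], fij)
    _scatter_rows(F, edges[:, 1], -fij)
    return F


def _spring_cached(pos: np.ndarray, edges: np.ndarray, i3: np.ndarray,
                   j3: np.ndarray, k_s: float, d0: float) -> np.ndarray:
    """Hot-path spring forces with precomputed scatter indices."""
    F = np.zeros_like(pos)
    if len(edges) == 0:
        return F
    dvec = pos[edges[:, 1]] - pos[edges[:, 0]]
    d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
    if d.min() <= 0.0:
        raise ValueError("zero-length edge: spring direction undefined")
    fij = (k_s * (d - d0) / d)[:, None] * dvec
    _scatter_flat(F, i3, fij)
    _scatter_flat(F, j3, -fij)
    return F


def spring_energy(pos: np.ndarray, edges: np.ndarray, k_s: float,
                  d0: float) -> float:
    """Total Hookean potential (k/2)(d - d0)^2 over the edge subset."""
    if len(edges) == 0:
        return 0.0
    d = np.linalg.norm(pos[edges[:, 1]] - pos[edges[:, 0]], axis=1)
    return float(0.5 * k_s * np.sum((d - d0) ** 2))


def _pair_angle_terms(geo: TriangleGeometry, theta0: float):
    """cos, signed sin and df/dcos of 1 - cos(theta - theta0) per pair."""
    pa, pb = geo.pair_local[:, 0], geo.pair_local[:, 1]
    na, nb = geo.normal[pa], geo.normal[pb]
    c = np.clip(np.einsum("ij,ij->i", na, nb), -1.0, 1.0)
    if theta0 == 0.0:
        return c, None, 1.0 - c, np.full(len(c), -1.0)
    sgn = np.sign(np.einsum("ij,ij->i", na - nb,
                            geo.center[pa] - geo.center[pb]))
    sgn[sgn == 0] = 1.0
    s = sgn * np.sqrt(np.maximum(1.0 - c * c, 0.0))
    f = 1.0 - c * np.cos(theta0) - s * np.sin(theta0)
    root = np.sqrt(np.maximum(1.0 - c * c, 1e-24))
    dfdc = -np.cos(theta0) + np.sin(theta0) * sgn * c / root
    return c, s, f, dfdc


def bending_energy(geo: TriangleGeometry, k_b: float, theta0: float) -> float:
    """Area-weighted discrete bending energy of the live mesh."""
    if len(geo.pair_local) == 0:
        return 0.0
    _, _, f, _ = _pair_angle_terms(geo, theta0)
    pa, pb = geo.pair_local[:, 0], geo.pair_local[:, 1]
    w = geo.area[pa] * geo.area[pb]
    return float(k_b * np.sum(f * w) / w.mean())


def _scatter_normal_gradient(F: np.ndarray, geo: TriangleGeometry,
                             pos: np.ndarray, q: np.ndarray,
                             tn_cat3=None) -> None:
    """Accumulate -dE/dr given per-triangle dE/dN vectors ``q``.

    For a triangle (a, b, c) with raw normal N = (b-a) x (c-a) and a
    scalar function E with dE/dN = q:
    dE/db = (c-a) x q, dE/dc = q x (b-a), dE/da = -(dE/db + dE/dc).
    """
    tn = geo.tri_nodes
    A, B, C = pos[tn[:, 0]], pos[tn[:, 1]], pos[tn[:, 2]]
    gB = _cross(C - A, q)
    gC = _cross(q, B - A)
    gA = -gB - gC
    if tn_cat3 is not None:
        _scatter_flat(F, tn_cat3, -np.concatenate([gA, gB, gC]))
    else:
        _scatter_rows(F, tn[:, 0], -gA)
        _scatter_rows(F, tn[:, 1], -gB)
        _scatter_rows(F, tn[:, 2], -gC)


def bending_energy_and_forces(state_or_geo, pos: np.ndarray, k_b: float,
                              theta0: float):
    """Bending energy and its exact negative gradient.

    The gradient runs through the dihedral cosines, the area-product
    weights and the mean-product normalisation, so a central finite
    difference of :func:`bending_energy` reproduces the force.
    """
    if isinstance(state_or_geo, SkeletonState):
        geo = membrane_triangles(state_or_geo)
    else:
        geo = state_or_geo
    F = np.zeros_like(pos)
    P = len(geo.pair_local)
    if P == 0:
        return 0.0, F
    c, _, f, dfdc = _pair_angle_terms(geo, theta0)
    pa, pb = geo.pair_local[:, 0], geo.pair_local[:, 1]
    Aa, Ab = geo.area[pa], geo.area[pb]
    w = Aa * Ab
    M = w.mean()
    S = np.sum(f * w)
    E = k_b * S / M

    T = geo.n_triangles
    # dE/dc_p routed through each triangle's unit normal
    dEdc = k_b * w / M * dfdc
    G = np.zeros((T, 3))
    if geo.pa3 is not None and len(geo.pa3) == 3 * P:
        _scatter_flat(G, geo.pa3, dEdc[:, None] * geo.normal[pb])
        _scatter_flat(G, geo.pb3, dEdc[:, None] * geo.normal[pa])
    else:
        _scatter_rows(G, pa, dEdc[:, None] * geo.normal[pb])
        _scatter_rows(G, pb, dEdc[:, None] * geo.normal[pa])
    nn = 2.0 * geo.area  # |N|
    q_c = (G - np.einsum("ij,ij->i", geo.normal, G)[:, None] * geo.normal) \
        / nn[:, None]
    # dE/dA_t from the weight and from the mean normalisation
    coef = k_b / M * (f - S / (M * P))
    dEdA = np.bincount(pa, weights=coef * Ab, minlength=T) \
        + np.bincount(pb, weights=coef * Aa, minlength=T)
    q = q_c + 0.5 * dEdA[:, None] * geo.normal
    _scatter_normal_gradient(F, geo, pos, q, tn_cat3=geo.tn_cat3)
    return float(E), F


def surface_area(pos: np.ndarray, tri_nodes: np.ndarray) -> float:
    """Total triangle area of a (sub)mesh, nm^2."""
    n = np.cross(pos[tri_nodes[:, 1]] - pos[tri_nodes[:, 0]],
                 pos[tri_nodes[:, 2]] - pos[tri_nodes[:, 0]])
    return float(0.5 * np.linalg.norm(n, axis=1).sum())


def area_energy(pos: np.ndarray, tri_nodes: np.ndarray, k_A: float,
                A0: float) -> float:
    A = surface_area(pos, tri_nodes)
    return float(0.5 * k_A * (A - A0) ** 2 / A0)


def area_constraint_force(pos: np.ndarray, tri_nodes: np.ndarray, k_A: float,
                          A0: float) -> np.ndarray:
    """Restoring force of the global surface-area constraint.

    ``F_i = -k_A (A - A0)/A0 * dA/dr_i``: zero at the reference area,
    shrinking an inflated surface and expanding a deflated one.
    """
    F = np.zeros_like(pos)
    a = pos[tri_nodes[:, 0]]
    b = pos[tri_nodes[:, 1]]
    c = pos[tri_nodes[:, 2]]
    N = _cross(b - a, c - a)
    nn = np.sqrt(np.einsum("ij,ij->i", N, N))
    A = float(0.5 * nn.sum())
    lam = k_A * (A - A0) / A0
    q = lam * 0.5 * N / nn[:, None]          # dE/dN per triangle
    gB = _cross(c - a, q)
    gC = _cross(q, b - a)
    gA = -gB - gC
    _scatter_rows(F, tri_nodes[:, 0], -gA)
    _scatter_rows(F, tri_nodes[:, 1], -gB)
    _scatter_rows(F, tri_nodes[:, 2], -gC)
    return F


def myosin_forces(state: SkeletonState, k_c_M: float,
                  geo: Optional[TriangleGeometry] = None) -> np.ndarray:
    """Contractile cable forces between live-triangle centers.

    Each cable of length ``d`` exerts tension ``k_c_M * d`` pulling the two
    centers together; the end force at each triangle is split equally among
    its three actin nodes.

    Raises
    ------
    RuntimeError
        If a cable references a triangle that is no longer live (the
        topology update must run before the force evaluation).
    """
    geo = geo if geo is not None else current_triangles(state,
                                                        geometry=False)
    F = np.zeros_like(state.pos)
    tn = state.base.tri_nodes
    for ta, tb in state.myosin_tris:
        if geo.base_to_local[ta] < 0 or geo.base_to_local[tb] < 0:
            raise RuntimeError("myosin cable references a dead triangle")
        na, nb = tn[ta], tn[tb]
        dvec = state.pos[nb].mean(axis=0) - state.pos[na].mean(axis=0)
        d = float(np.linalg.norm(dvec))
        if d <= 1e-12:
            continue
        fa = (k_c_M * d / 3.0) * (dvec / d)   # on each node of triangle a
        F[na] += fa
        F[nb] -= fa
    return F


def myosin_energy(state: SkeletonState, k_c_M: float,
                  geo: Optional[TriangleGeometry] = None) -> float:
    """Cable potential (k_c_M/2) d^2 summed over myosin edges."""
    tn = state.base.tri_nodes
    e = 0.0
    for ta, tb in state.myosin_tris:
        d = np.linalg.norm(state.pos[tn[tb]].mean(axis=0)
                           - state.pos[tn[ta]].mean(axis=0))
        e += 0.5 * k_c_M * d * d
    return float(e)


def total_force(state: SkeletonState, p: Params, flags: FeatureFlags,
                A0: Optional[float] = None) -> ForceField:
    """Assemble the per-node force balance for the enabled modules."""
    pos = state.pos
    geo = current_triangles(state, geometry=not _K.HAVE_NUMBA)
    ch = state.caches
    zeros = np.zeros_like(pos)
    if _K.HAVE_NUMBA:
        f_s = np.zeros_like(pos)
        _K.spring_kernel(pos, ch["spectrin_edges"], p.k_s_S, p.d0_S, f_s)
        if len(state.conn):
            f_c = np.zeros_like(pos)
            _K.spring_kernel(pos, state.conn, p.k_s_C, state.conn_d0, f_c)
        else:
            f_c = zeros.copy()
        e_b, f_b = 0.0, zeros.copy()
        if flags.bending:
            mem = membrane_triangles(state, geometry=False)
            e_b = float(_K.bending_kernel(pos, mem.tri_nodes,
                                          mem.pair_local, p.k_b, p.theta0,
                                          f_b))
    else:
        f_s = _spring_cached(pos, ch["spectrin_edges"], ch["sp_i3"],
                             ch["sp_j3"], p.k_s_S, p.d0_S)
        f_c = (_spring_cached(pos, state.conn, ch["cn_i3"], ch["cn_j3"],
                              p.k_s_C, state.conn_d0)
               if len(state.conn) else zeros.copy())
        e_b, f_b = 0.0, zeros.copy()
        if flags.bending:
            e_b, f_b = bending_energy_and_forces(state, pos, p.k_b, p.theta0)
    f_a, area = zeros.copy(), 0.0
    if flags.area_constraint:
        if A0 is None:
            raise ValueError("area constraint enabled but A0 not provided")
        tris = state.base.tri_nodes
        if _K.HAVE_NUMBA:
            area = float(_K.area_kernel(pos, tris, p.k_A, A0, f_a))
        else:
            area = surface_area(pos, tris)
            f_a = area_constraint_force(pos, tris, p.k_A, A0)
    f_m = (myosin_forces(state, p.k_c_M)
           if flags.myosin and state.myosin_tris else zeros.copy())
    return ForceField(f_spring_S=f_s, f_spring_C=f_c, f_bend=f_b,
                      f_area=f_a, f_myosin=f_m, e_b=e_b, area=area,
                      area0=A0 or 0.0)
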