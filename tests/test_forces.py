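import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import memskel as mk
from memskel.forces import (FeatureFlags, area_constraint_force, area_energy,
                            bending_energy, bending_energy_and_forces,
                            myosin_energy, myosin_forces, spring_energy,
                            spring_forces, surface_area, total_force)
from memskel.state import membrane_triangles, rebuild_triangles
from conftest import finite_difference_gradient

TOL = 1e-4   # relative error vs central finite differences


def _bend_energy_fn(st, k_b, theta0):
    def e(pos):
        st.pos = pos
        st.membrane = None
        return bending_energy(membrane_triangles(st), k_b, theta0)
    return e


@pytest.mark.parametrize("theta0_deg", [0.0, 20.0])
def test_bending_force_matches_finite_difference(wrinkled_patch, theta0_deg):
    st = wrinkled_patch
    th = math.radians(theta0_deg)
    pos0 = st.pos.copy()
    _, F = bending_energy_and_forces(st, pos0, 820.0, th)
    G = finite_difference_gradient(_bend_energy_fn(st, 820.0, th), pos0)
    assert np.abs(F + G).max() / np.abs(G).max() < TOL


def test_area_force_matches_finite_difference(wrinkled_patch):
    st = wrinkled_patch
    tris = st.base.tri_nodes
    A0 = 0.9 * surface_area(st.pos, tris)
    F = area_constraint_force(st.pos, tris, 0.038, A0)
    G = finite_difference_gradient(
        lambda pos: area_energy(pos, tris, 0.038, A0), st.pos.copy())
    assert np.abs(F + G).max() / np.abs(G).max() < TOL


def test_spring_force_matches_finite_difference(wrinkled_patch):
    st = wrinkled_patch
    F = spring_forces(st.pos, st.edges, 1.0, 180.0)
    G = finite_difference_gradient(
        lambda pos: spring_energy(pos, st.edges, 1.0, 180.0), st.pos.copy())
    assert np.abs(F + G).max() / np.abs(G).max() < TOL


def test_myosin_force_matches_finite_difference(wrinkled_patch):
    st = wrinkled_patch
    geo = rebuild_triangles(st)
    st.myosin_tris = [[int(geo.alive[0]), int(geo.alive[-1])]]
    st.myosin_birth = [0.0]
    F = myosin_forces(st, 0.1071)
    G = finite_difference_gradient(
        lambda pos: _myosin_e(st, pos), st.pos.copy())
    assert np.abs(F + G).max() / np.abs(G).max() < TOL


def _myosin_e(st, pos):
    st.pos = pos
    return myosin_energy(st, 0.1071)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(d=hst.floats(30.0, 500.0),
       theta=hst.floats(0.0, 2 * math.pi),
       phi=hst.floats(-1.5, 1.5))
def test_spring_force_law_any_orientation(d, theta, phi):
    """|F| = k|d - d0| along the edge axis; sign flips at the rest length;
    the pair force always sums to zero."""
    u = np.array([math.cos(theta) * math.cos(phi),
                  math.sin(theta) * math.cos(phi), math.sin(phi)])
    pos = np.vstack([np.zeros(3), d * u])
    F = spring_forces(pos, np.array([[0, 1]]), 1.0, 180.0)
    np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(F[0]), abs(d - 180.0),
                               rtol=1e-9, atol=1e-9)
    axial = F[0] @ u
    if d > 180.0:
        assert axial > 0          # contractile: node 0 pulled toward node 1
    elif d < 180.0:
        assert axial < 0          # expansive: pushed apart


@settings(derandomize=True, max_examples=10, deadline=None)
@given(seed=hst.integers(0, 10 ** 6))
def test_bending_energy_rigid_motion_invariance(seed):
    rng = np.random.default_rng(seed)
    st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=3, cols=4))
    st.pos = st.pos + rng.normal(0, 15.0, st.pos.shape)
    st.membrane = None
    e0 = bending_energy(membrane_triangles(st), 820.0, 0.3)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    st.pos = st.pos @ R.T + rng.normal(0, 300.0, 3)
    st.membrane = None
    e1 = bending_energy(membrane_triangles(st), 820.0, 0.3)
    assert e1 == pytest.approx(e0, rel=1e-8)


class TestSpringExamples:
    def test_rest_length_gives_zero_force(self):
        pos = np.array([[0.0, 0, 0], [180.0, 0, 0]])
        F = spring_forces(pos, np.array([[0, 1]]), 1.0, 180.0)
        assert np.abs(F).max() == 0.0

    def test_stretched_edge_pulls_nodes_together(self):
        pos = np.array([[0.0, 0, 0], [190.0, 0, 0]])
        F = spring_forces(pos, np.array([[0, 1]]), 1.0, 180.0)
        np.testing.assert_allclose(F[0], [10.0, 0, 0])
        np.testing.assert_allclose(F[1], [-10.0, 0, 0])

    def test_slightly_compressed_edge_pushes_past_threshold(self, params):
        pos = np.array([[0.0, 0, 0], [179.9, 0, 0]])
        F = spring_forces(pos, np.array([[0, 1]]), 1.0, 180.0)
        np.testing.assert_allclose(F[0], [-0.1, 0, 0], atol=1e-12)
        assert np.linalg.norm(F[0]) > params.F_th

    def test_zero_length_edge_rejected(self):
        pos = np.zeros((2, 3))
        with pytest.raises(ValueError):
            spring_forces(pos, np.array([[0, 1]]), 1.0, 180.0)


class TestBendingExamples:
    def test_coplanar_pair_is_the_flat_minimum(self, hinge):
        hinge.pos[3, 1] = -180.0 * math.sqrt(3) / 2
        hinge.pos[3, 2] = 0.0
        e, F = bending_energy_and_forces(hinge, hinge.pos, 820.0, 0.0)
        assert e == pytest.approx(0.0, abs=1e-9)
        assert np.abs(F).max() < 1e-9

    def test_sixty_degree_hinge_energy(self, hinge):
        geo = rebuild_triangles(hinge)
        e = bending_energy(geo, 820.0, 0.0)
        assert e == pytest.approx(820.0 * (1 - math.cos(math.radians(60))),
                                  rel=1e-9)

    def test_energy_invariant_under_rigid_motion(self, wrinkled_patch):
        st = wrinkled_patch
        e0 = bending_energy(membrane_triangles(st), 820.0, 0.0)
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        st.pos = st.pos @ R.T + np.array([100.0, -50.0, 30.0])
        st.membrane = None
        e1 = bending_energy(membrane_triangles(st), 820.0, 0.0)
        assert abs(e1 - e0) / e0 < 1e-8

    def test_degenerate_triangle_rejected(self, hinge):
        hinge.pos[2] = hinge.pos[0]     # collapse one face
        hinge.membrane = None
        with pytest.raises(FloatingPointError):
            bending_energy_and_forces(hinge, hinge.pos, 820.0, 0.0)


class TestAreaExamples:
    def test_zero_force_at_reference_area(self, wrinkled_patch):
        tris = wrinkled_patch.base.tri_nodes
        A0 = surface_area(wrinkled_patch.pos, tris)
        F = area_constraint_force(wrinkled_patch.pos, tris, 0.038, A0)
        assert np.abs(F).max() < 1e-12

    def test_inflated_sphere_pulled_inward(self):
        sp = mk.build_sphere_mesh(mk.MeshSpec(kind="SPHERE"))
        tris = sp.base.tri_nodes
        A0 = surface_area(sp.pos, tris) / 1.1
        F = area_constraint_force(sp.pos, tris, 0.038, A0)
        radial = np.einsum("ij,ij->i", F, sp.pos)
        assert (radial < 0).mean() > 0.99   # net inward on every node


class TestMyosinExamples:
    def test_tension_law_and_equal_split(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=3, cols=6))
        geo = rebuild_triangles(st)
        centers = st.pos[st.base.tri_nodes[geo.alive]].mean(axis=1)
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        # nearest pair to 200 nm with disjoint node sets (clean 1/3 split)
        best, (i, j) = np.inf, (0, 0)
        for a in range(len(centers)):
            for b in range(len(centers)):
                if a == b or set(st.base.tri_nodes[geo.alive[a]]) \
                        & set(st.base.tri_nodes[geo.alive[b]]):
                    continue
                if abs(d[a, b] - 200.0) < best:
                    best, (i, j) = abs(d[a, b] - 200.0), (a, b)
        ta, tb = int(geo.alive[i]), int(geo.alive[j])
        st.myosin_tris = [[ta, tb]]
        st.myosin_birth = [0.0]
        F = myosin_forces(st, params.k_c_M)
        dk = d[i, j]
        na = st.base.tri_nodes[ta]
        u = (centers[j] - centers[i]) / dk
        for node in na:
            np.testing.assert_allclose(F[node] @ u,
                                       params.k_c_M * dk / 3.0, rtol=1e-9)
        # contractile only: pulls the a-side toward the b-side
        assert (F[na].sum(axis=0) @ u) > 0

    def test_newtons_third_law(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=3, cols=6))
        geo = rebuild_triangles(st)
        st.myosin_tris = [[int(geo.alive[0]), int(geo.alive[-1])]]
        st.myosin_birth = [0.0]
        F = myosin_forces(st, params.k_c_M)
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-10)

    def test_dead_triangle_reference_rejected(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=3, cols=6))
        geo = rebuild_triangles(st)
        ta = int(geo.alive[0])
        st.myosin_tris = [[ta, int(geo.alive[-1])]]
        st.myosin_birth = [0.0]
        st.bound[st.base.tri_edges[ta][0]] = False
        st.topology_dirty = True
        with pytest.raises(RuntimeError):
            myosin_forces(st, params.k_c_M)


class TestTotalForce:
    def test_all_flags_off_on_rest_patch_gives_zero(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH"))
        ff = total_force(st, params, FeatureFlags(bending=False))
        assert np.abs(ff.f_total).max() < 1e-9

    def test_shear_start_loads_only_linker_nodes(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH"))
        mk.attach_connectors(st, mk.SHEAR, params, d0_C=params.d0_C3)
        ff = total_force(st, params, FeatureFlags(bending=True))
        loaded = (np.abs(ff.f_total).max(axis=1) > 1e-9) & st.mobile
        assert set(np.flatnonzero(loaded)) == set(st.conn[:, 0])

    def test_total_is_sum_of_components(self, wrinkled_patch, params):
        ff = total_force(wrinkled_patch, params, FeatureFlags(bending=True))
        np.testing.assert_allclose(
            ff.f_total,
            ff.f_spring_S + ff.f_spring_C + ff.f_myosin + ff.f_bend
            + ff.f_area)

    def test_free_mesh_forces_sum_to_zero(self, wrinkled_patch, params):
        ff = total_force(wrinkled_patch, params, FeatureFlags(bending=True))
        np.testing.assert_allclose(ff.f_total.sum(axis=0), 0.0, atol=1e-8)


def test_jit_kernels_match_reference_implementation(params):
    """The fused kernels agree with the numpy reference path."""
    from memskel import _kernels as K
    if not K.HAVE_NUMBA:
        pytest.skip("numba unavailable; single path only")
    st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH"))
    mk.attach_connectors(st, mk.SHEAR, params, d0_C=params.d0_C3)
    rng = np.random.default_rng(3)
    st.pos[st.mobile] += rng.normal(0, 8.0, st.pos[st.mobile].shape)
    st.topology_dirty = True
    st.membrane = None
    fl = FeatureFlags(bending=True)
    ff_k = total_force(st, params, fl)
    K.HAVE_NUMBA = False
    try:
        ff_n = total_force(st, params, fl)
    finally:
        K.HAVE_NUMBA = True
    for name in ("f_spring_S", "f_spring_C", "f_bend"):
        np.testing.assert_allclose(getattr(ff_k, name),
                                   getattr(ff_n, name), atol=1e-10)
    assert ff_k.e_b == pytest.approx(ff_n.e_b, rel=1e-12)
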