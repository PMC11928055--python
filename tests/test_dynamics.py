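import dataclasses

import numpy as np
import pytest

import memskel as mk
from memskel import metrics
from memskel.dynamics import (ExclusionRegion, apply_volume_exclusion,
                              euler_step, release_connectors, simulate)
from memskel.forces import FeatureFlags, total_force
from memskel.state import membrane_triangles


class TestEulerStep:
    def test_zero_force_leaves_positions(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=3, cols=3))
        pos0 = st.pos.copy()
        euler_step(st, np.zeros_like(st.pos), params.zeta, params.dt)
        np.testing.assert_array_equal(st.pos, pos0)

    def test_displacement_is_force_dt_over_zeta(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=3, cols=3))
        F = np.zeros_like(st.pos)
        F[0] = [1.25, 0.0, 0.0]
        pos0 = st.pos[0].copy()
        euler_step(st, F, 1.25, 0.002)
        np.testing.assert_allclose(st.pos[0] - pos0, [0.002, 0, 0])

    def test_fixed_nodes_never_move(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH"))
        mk.attach_connectors(st, mk.ISOTROPIC, params, d0_C=params.d0_C2)
        adh = np.flatnonzero(~st.mobile)
        pos0 = st.pos[adh].copy()
        sc = mk.make_scenario("ISO_EXTENSION", params)
        st2, _, _ = simulate(sc, params, T=2.0, seed=0)
        np.testing.assert_array_equal(st2.pos[~st2.mobile], pos0)

    def test_nonfinite_force_aborts(self, params):
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=3, cols=3))
        F = np.zeros_like(st.pos)
        F[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            euler_step(st, F, params.zeta, params.dt)

    def test_two_node_spring_matches_closed_form(self, params):
        """Extension decays as exp(-2kt/zeta) for an isolated spring."""
        from memskel.state import SkeletonState, build_base_topology
        pos = np.array([[0.0, 0, 0], [230.0, 0, 0]])
        edges = np.array([[0, 1]])
        kind = np.zeros(2, np.int8)
        base = build_base_topology(edges, np.empty((0, 3), np.int64), kind)
        st = SkeletonState(pos=pos, prev_pos=pos.copy(), kind=kind,
                           mobile=np.ones(2, bool), edges=edges,
                           bound=np.ones(1, bool), base=base,
                           conn=np.empty((0, 2), np.int64))
        k, zeta, dt = params.k_s_S, params.zeta, params.dt
        for _ in range(int(5.0 / dt)):
            F = mk.spring_forces(st.pos, st.edges, k, params.d0_S)
            euler_step(st, F, zeta, dt)
        ext = st.edge_lengths()[0] - params.d0_S
        # forward Euler at dt=0.002 carries ~1.3% discretisation error here
        expected = 50.0 * np.exp(-2.0 * k * 5.0 / zeta)
        assert ext == pytest.approx(expected, rel=0.02)
        exact_discrete = 50.0 * (1.0 - 2.0 * k * dt / zeta) ** int(5.0 / dt)
        assert ext == pytest.approx(exact_discrete, rel=1e-9)


@pytest.fixture(scope="module")
def region():
    sp = mk.build_sphere_mesh(mk.MeshSpec(kind="SPHERE"))
    return sp, ExclusionRegion(sp.pos, sp.base.tri_nodes, 0.15)


class TestVolumeExclusion:

    def test_region_volume_is_85_percent(self, region):
        sp, reg = region
        v0 = metrics.enclosed_volume(sp.pos, sp.base.tri_nodes)
        assert reg.volume == pytest.approx(0.85 * v0, rel=0.01)

    def test_inward_mover_is_reverted(self, region, params):
        sp, reg = region
        st = sp.copy()
        st.prev_pos = st.pos.copy()
        st.pos[0] *= 0.5                     # jumped deep inside
        apply_volume_exclusion(st, reg)
        np.testing.assert_array_equal(st.pos[0], st.prev_pos[0])

    def test_outside_mover_untouched(self, region):
        sp, reg = region
        st = sp.copy()
        st.prev_pos = st.pos.copy()
        st.pos[0] *= 1.05                    # moved outward
        moved = st.pos[0].copy()
        apply_volume_exclusion(st, reg)
        np.testing.assert_array_equal(st.pos[0], moved)

    def test_disabled_region_is_identity(self, region):
        sp, _ = region
        st = sp.copy()
        st.pos[0] *= 0.5
        moved = st.pos[0].copy()
        apply_volume_exclusion(st, None)
        np.testing.assert_array_equal(st.pos[0], moved)

    def test_exclusion_never_increases_displacement(self, params):
        sc = mk.make_scenario("SUSPENDED_CELL", params)
        state = sc.build(params)
        state.rng = np.random.default_rng(0)
        reg = ExclusionRegion(state.pos, state.base.tri_nodes, 0.15)
        for _ in range(50):
            ff = total_force(state, params, sc.flags,
                             A0=mk.surface_area(state.pos,
                                                state.base.tri_nodes))
            euler_step(state, ff.f_total, params.zeta, params.dt)
            before = np.linalg.norm(state.pos - state.prev_pos, axis=1)
            apply_volume_exclusion(state, reg)
            after = np.linalg.norm(state.pos - state.prev_pos, axis=1)
            assert (after <= before + 1e-12).all()


class TestSimulate:
    def test_equilibrium_patch_is_preserved(self, params):
        sc = mk.make_scenario("SHEAR", params, unbinding=False,
                              rebinding=False, myosin=False)
        sc = dataclasses.replace(sc, release_time=None)
        state = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH"))
        pos0 = state.pos.copy()
        out, _, _ = simulate(sc, params, T=1.0, seed=0, state=state)
        np.testing.assert_allclose(out.pos, pos0, atol=1e-9)

    def test_deterministic_without_rng(self, params):
        sc = mk.make_scenario("SHEAR", params, myosin=False)
        _, s1, _ = simulate(sc, params, T=5.0, seed=3)
        _, s2, _ = simulate(sc, params, T=5.0, seed=4)
        assert s1.equals(s2)      # no stochastic module active

    def test_seeded_runs_bit_identical(self, params):
        sc = mk.make_scenario("SUSPENDED_CELL", params)
        st1, s1, e1 = simulate(sc, params, T=2.0, seed=7)
        st2, s2, e2 = simulate(sc, params, T=2.0, seed=7)
        assert s1.equals(s2)
        np.testing.assert_array_equal(st1.pos, st2.pos)
        assert [(t, ev.myosin_added) for t, ev in e1] == \
            [(t, ev.myosin_added) for t, ev in e2]

    def test_energy_descent_bending_only_patch(self, params):
        """Deterministic relaxation dissipates spring + bending energy."""
        from memskel.forces import bending_energy, spring_energy
        st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=5, cols=6))
        rng = np.random.default_rng(4)
        st.pos = st.pos + rng.normal(0, 10.0, st.pos.shape)
        st.topology_dirty = True
        fl = FeatureFlags(bending=True)
        energies = []
        for step in range(3000):
            ff = total_force(st, params, fl)
            euler_step(st, ff.f_total, params.zeta, params.dt)
            if step % 100 == 0:
                e = spring_energy(st.pos, st.edges, params.k_s_S,
                                  params.d0_S) \
                    + bending_energy(membrane_triangles(st), params.k_b,
                                     params.theta0)
                energies.append(e)
        diffs = np.diff(energies)
        assert (diffs <= 1e-9 * energies[0]).all()

    def test_halving_dt_converges(self, params):
        """Forward-Euler convergence on the remodeling-free shear run."""
        sc = mk.make_scenario("SHEAR", params, unbinding=False,
                              rebinding=False, myosin=False)
        sc = dataclasses.replace(sc, release_time=None)
        st1, _, _ = simulate(sc, params, T=20.0, seed=1)
        st2, _, _ = simulate(sc, params.replace(dt=0.001), T=20.0, seed=1)
        rms = np.sqrt(((st1.pos - st2.pos) ** 2).sum(axis=1).mean())
        assert rms < 0.1


class TestRelease:
    def test_release_removes_connectors_and_anchors(self, params):
        sc = mk.make_scenario("SHEAR", params, myosin=False)
        st = sc.build(params)
        n_linkers = (st.kind == mk.LINKER).sum()
        release_connectors(st)
        assert len(st.conn) == 0
        assert (st.kind != mk.ADHESION_FIXED).all()
        assert (st.kind == mk.LINKER).sum() == n_linkers
        assert st.mobile.all()

    def test_release_is_idempotent_with_warning(self, params):
        sc = mk.make_scenario("SHEAR", params, myosin=False)
        st = sc.build(params)
        release_connectors(st)
        n = st.n_nodes
        with pytest.warns(UserWarning):
            release_connectors(st)
        assert st.n_nodes == n
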