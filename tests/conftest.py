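"""Shared fixtures: small force-check fixtures and cached reference runs."""

from __future__ import annotations

import numpy as np
import pytest

import memskel as mk
from memskel import Params


@pytest.fixture(scope="session")
def params() -> Params:
    return Params()


@pytest.fixture()
def wrinkled_patch(params):
    """Small (16-node) patch pushed out of plane; force-gradient fixture."""
    st = mk.build_patch_mesh(mk.MeshSpec(kind="PATCH", rows=4, cols=4))
    rng = np.random.default_rng(0)
    st.pos = st.pos + rng.normal(0, 12.0, st.pos.shape)
    st.topology_dirty = True
    st.membrane = None
    return st


@pytest.fixture()
def hinge():
    """Two triangles sharing an edge, one face rotated 60 degrees."""
    import math

    from memskel.state import SkeletonState, build_base_topology

    h = 180.0 * math.sqrt(3.0) / 2.0
    pos = np.array([[0.0, 0.0, 0.0], [180.0, 0.0, 0.0],
                    [90.0, h, 0.0], [90.0, -h, 0.0]])
    edges = np.array([[0, 1], [0, 2], [1, 2], [0, 3], [1, 3]])
    tris = np.array([[0, 1, 2], [0, 3, 1]])
    kind = np.zeros(4, np.int8)
    th = math.radians(60.0)
    y, z = pos[3, 1], pos[3, 2]
    pos[3, 1] = y * math.cos(th) + z * math.sin(th)
    pos[3, 2] = -y * math.sin(th) + z * math.cos(th)
    base = build_base_topology(edges, tris, kind)
    return SkeletonState(pos=pos, prev_pos=pos.copy(), kind=kind,
                         mobile=np.ones(4, bool), edges=edges,
                         bound=np.ones(5, bool), base=base,
                         conn=np.empty((0, 2), np.int64))


def finite_difference_gradient(energy, pos, h=1e-5):
    """Central finite difference of a scalar energy over all coordinates."""
    G = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for k in range(3):
            pp = pos.copy()
            pp[i, k] += h
            pm = pos.copy()
            pm[i, k] -= h
            G[i, k] = (energy(pp) - energy(pm)) / (2.0 * h)
    return G


# ---- cached reference runs (shared by scenario and acceptance tests) ----

@pytest.fixture(scope="session")
def shear_unbind_only(params):
    """Reference shear run, unbinding only (120 s attached + 120 s free)."""
    sc = mk.make_scenario("SHEAR", params, myosin=False, rebinding=False)
    return mk.simulate(sc, params, seed=1)


@pytest.fixture(scope="session")
def shear_unbind_rebind(params):
    """Reference shear run with unbinding and rebinding, no myosin."""
    sc = mk.make_scenario("SHEAR", params, myosin=False)
    return mk.simulate(sc, params, seed=1)


@pytest.fixture(scope="session")
def myosin_shear_replicates(params):
    """Five seeded replicates of the full myosin shear-and-release run."""
    sc = mk.make_scenario("SHEAR", params)
    results, summary = mk.run_replicates(sc, params, n_reps=5, base_seed=100)
    return results, summary
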