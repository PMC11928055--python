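"""Observables and statistics reported by the simulations.

Distribution summaries follow box-plot conventions: median, quartiles by
linear interpolation between order statistics (the "type 7" estimator),
IQR = Q3 - Q1, and outlier fences at 1.5 IQR beyond the quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .state import ACTIN, SkeletonState, membrane_triangles


@dataclass
class DistributionStats:
    median: float
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float


def distribution_stats(values: Sequence[float]) -> DistributionStats:
    """Box-plot summary of a non-empty sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    return DistributionStats(median=float(med), q1=float(q1), q3=float(q3),
                             iqr=float(iqr),
                             lower_fence=float(q1 - 1.5 * iqr),
                             upper_fence=float(q3 + 1.5 * iqr))


def iqr(values: Sequence[float]) -> float:
    return distribution_stats(values).iqr


def percent_attached(state: SkeletonState) -> float:
    """100 x bound spectrin edges / initial spectrin edge count."""
    return 100.0 * state.n_bound / state.n_edges


def bound_lengths(state: SkeletonState) -> np.ndarray:
    """Current lengths of the bound spectrin edges, nm."""
    return state.edge_lengths(np.flatnonzero(state.bound))


def actin_heights(state: SkeletonState) -> np.ndarray:
    """z-coordinates of the F-actin nodes, nm."""
    return state.pos[state.kind == ACTIN, 2].copy()


def membrane_force_magnitudes(state: SkeletonState, f_membrane: np.ndarray,
                              ) -> np.ndarray:
    """|F_mem| per ACTIN node of the membrane triangulation.

    Linker and adhesion nodes receive no membrane force by construction
    and are excluded; the membrane triangulation is fixed, so the sample
    size is constant over a run.
    """
    geo = membrane_triangles(state, geometry=False)
    in_tri = np.zeros(state.n_nodes, dtype=bool)
    if geo.n_triangles:
        in_tri[np.unique(geo.tri_nodes)] = True
    sample = in_tri & (state.kind == ACTIN)
    return np.linalg.norm(f_membrane[sample], axis=1)


def enclosed_volume(pos: np.ndarray, tri_nodes: np.ndarray) -> float:
    """Signed volume of a closed, outward-oriented triangulation (nm^3)."""
    a, b, c = pos[tri_nodes[:, 0]], pos[tri_nodes[:, 1]], pos[tri_nodes[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def volume_centroid(pos: np.ndarray, tri_nodes: np.ndarray) -> np.ndarray:
    """Volumetric centroid of a closed triangulation."""
    a, b, c = pos[tri_nodes[:, 0]], pos[tri_nodes[:, 1]], pos[tri_nodes[:, 2]]
    v = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    ctr = (a + b + c) / 4.0          # tetrahedra against the origin
    return (v[:, None] * ctr).sum(axis=0) / v.sum()


def projected_area(state: SkeletonState) -> float:
    """Area of the convex hull of the actin nodes' (x, y) footprint, nm^2."""
    xy = state.pos[state.kind == ACTIN, :2]
    try:
        return float(ConvexHull(xy).volume)   # 2-D hull: volume is the area
    except QhullError:
        return 0.0


def shape_metrics(state: SkeletonState) -> Tuple[float, float, float]:
    """(enclosed volume, projected area, height) of the current shape.

    Volume is evaluated on the full initial triangulation at the current
    positions (the bound sub-mesh is not closed once edges unbind) and is
    only defined for closed meshes.
    """
    if not state.base.closed:
        raise ValueError("enclosed volume requires a closed mesh")
    vol = enclosed_volume(state.pos, state.base.tri_nodes)
    z = state.pos[state.kind == ACTIN, 2]
    return vol, projected_area(state), float(z.max() - z.min())


def myosin_accounting(events: Iterable, series=None):
    """Myosin count series and the (uncensored) lifetime sample.

    Lifetimes are removal time minus birth time for removed cables only;
    cables alive at the end of the run are censored and excluded.
    """
    lifetimes = []
    for _t, ev in events:
        lifetimes.extend(life for _reason, life in ev.myosin_removed)
    counts = None
    if series is not None and "myosin_count" in series:
        counts = series[["time", "myosin_count"]]
    return counts, np.asarray(lifetimes, dtype=float)


def wilcoxon_median_test(sample: Sequence[float], reference: float):
    """Wilcoxon signed-rank test of ``median(sample - reference) == 0``."""
    diffs = np.asarray(sample, dtype=float) - reference
    if diffs.size < 5:
        raise ValueError("need at least 5 observations")
    if np.all(diffs == 0):
        raise ValueError("degenerate sample: all differences are zero")
    res = stats.wilcoxon(diffs)
    return res.statistic, res.pvalue


def one_sample_t_test(sample: Sequence[float], reference: float):
    """Two-tailed one-sample t-test against a scalar reference."""
    v = np.asarray(sample, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 observations")
    if np.std(v, ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance")
    res = stats.ttest_1samp(v, reference)
    return res.statistic, res.pvalue


def significance_tests(sample: Sequence[float], reference: float) -> dict:
    """Both reported tests on one sample vs a scalar reference."""
    w, wp = wilcoxon_median_test(sample, reference)
    t, tp = one_sample_t_test(sample, reference)
    return {"wilcoxon_W": float(w), "wilcoxon_p": float(wp),
            "t_stat": float(t), "t_p": float(tp)}
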