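"""JIT-compiled hot loops for the per-step force evaluation.

The numpy implementations in :mod:`memskel.forces` are the reference; the
kernels here compute the same quantities loop-fused for speed and are used
by ``total_force`` when numba is importable. Results agree with the numpy
path to floating-point rounding (different summation order only).
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def spring_kernel(pos, edges, k_s, d0, F):          # pragma: no cover
    for e in range(edges.shape[0]):
        i = edges[e, 0]
        j = edges[e, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d <= 0.0:
            raise ValueError("zero-length edge: spring direction undefined")
        coef = k_s * (d - d0) / d
        F[i, 0] += coef * dx
        F[i, 1] += coef * dy
        F[i, 2] += coef * dz
        F[j, 0] -= coef * dx
        F[j, 1] -= coef * dy
        F[j, 2] -= coef * dz


@njit(cache=True)
def bending_kernel(pos, tri, pairs, k_b, theta0, F):   # pragma: no cover
    """Bending energy and exact-gradient force; returns the energy."""
    T = tri.shape[0]
    P = pairs.shape[0]
    if P == 0:
        return 0.0
    area = np.empty(T)
    nrm = np.empty((T, 3))
    ctr = np.empty((T, 3))
    rawn = np.empty(T)
    for t in range(T):
        ia, ib, ic = tri[t, 0], tri[t, 1], tri[t, 2]
        e1x = pos[ib, 0] - pos[ia, 0]
        e1y = pos[ib, 1] - pos[ia, 1]
        e1z = pos[ib, 2] - pos[ia, 2]
        e2x = pos[ic, 0] - pos[ia, 0]
        e2y = pos[ic, 1] - pos[ia, 1]
        e2z = pos[ic, 2] - pos[ia, 2]
        nx = e1y * e2z - e1z * e2y
        ny = e1z * e2x - e1x * e2z
        nz = e1x * e2y - e1y * e2x
        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
        if nn <= 0.0:
            raise FloatingPointError("degenerate (zero-area) triangle")
        rawn[t] = nn
        area[t] = 0.5 * nn
        nrm[t, 0] = nx / nn
        nrm[t, 1] = ny / nn
        nrm[t, 2] = nz / nn
        ctr[t, 0] = (pos[ia, 0] + pos[ib, 0] + pos[ic, 0]) / 3.0
        ctr[t, 1] = (pos[ia, 1] + pos[ib, 1] + pos[ic, 1]) / 3.0
        ctr[t, 2] = (pos[ia, 2] + pos[ib, 2] + pos[ic, 2]) / 3.0
    cos0 = math.cos(theta0)
    sin0 = math.sin(theta0)
    cp = np.empty(P)
    wp = np.empty(P)
    fp = np.empty(P)
    dfdc = np.empty(P)
    wsum = 0.0
    S = 0.0
    for p in range(P):
        a, b = pairs[p, 0], pairs[p, 1]
        c = (nrm[a, 0] * nrm[b, 0] + nrm[a, 1] * nrm[b, 1]
             + nrm[a, 2] * nrm[b, 2])
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        if theta0 == 0.0:
            f = 1.0 - c
            dd = -1.0
        else:
            sgn = ((nrm[a, 0] - nrm[b, 0]) * (ctr[a, 0] - ctr[b, 0])
                   + (nrm[a, 1] - nrm[b, 1]) * (ctr[a, 1] - ctr[b, 1])
                   + (nrm[a, 2] - nrm[b, 2]) * (ctr[a, 2] - ctr[b, 2]))
            sg = 1.0 if sgn >= 0.0 else -1.0
            s = sg * math.sqrt(max(1.0 - c * c, 0.0))
            f = 1.0 - c * cos0 - s * sin0
            root = math.sqrt(max(1.0 - c * c, 1e-24))
            dd = -cos0 + sin0 * sg * c / root
        w = area[a] * area[b]
        cp[p] = c
        wp[p] = w
        fp[p] = f
        dfdc[p] = dd
        wsum += w
        S += f * w
    M = wsum / P
    E = k_b * S / M
    G = np.zeros((T, 3))
    dEdA = np.zeros(T)
    for p in range(P):
        a, b = pairs[p, 0], pairs[p, 1]
        dc = k_b * wp[p] / M * dfdc[p]
        for k in range(3):
            G[a, k] += dc * nrm[b, k]
            G[b, k] += dc * nrm[a, k]
        cA = k_b / M * (fp[p] - S / (M * P))
        dEdA[a] += cA * area[b]
        dEdA[b] += cA * area[a]
    for t in range(T):
        ia, ib, ic = tri[t, 0], tri[t, 1], tri[t, 2]
        ndg = (nrm[t, 0] * G[t, 0] + nrm[t, 1] * G[t, 1]
               + nrm[t, 2] * G[t, 2])
        qx = (G[t, 0] - ndg * nrm[t, 0]) / rawn[t] + 0.5 * dEdA[t] * nrm[t, 0]
        qy = (G[t, 1] - ndg * nrm[t, 1]) / rawn[t] + 0.5 * dEdA[t] * nrm[t, 1]
        qz = (G[t, 2] - ndg * nrm[t, 2]) / rawn[t] + 0.5 * dEdA[t] * nrm[t, 2]
        ax, ay, az = pos[ia, 0], pos[ia, 1], pos[ia, 2]
        ux = pos[ib, 0] - ax
        uy = pos[ib, 1] - ay
        uz = pos[ib, 2] - az
        vx = pos[ic, 0] - ax
        vy = pos[ic, 1] - ay
        vz = pos[ic, 2] - az
        # gB = v x q ; gC = q x u ; gA = -gB - gC
        gBx = vy * qz - vz * qy
        gBy = vz * qx - vx * qz
        gBz = vx * qy - vy * qx
        gCx = qy * uz - qz * uy
        gCy = qz * ux - qx * uz
        gCz = qx * uy - qy * ux
        F[ib, 0] -= gBx
        F[ib, 1] -= gBy
        F[ib, 2] -= gBz
        F[ic, 0] -= gCx
        F[ic, 1] -= gCy
        F[ic, 2] -= gCz
        F[ia, 0] += gBx + gCx
        F[ia, 1] += gBy + gCy
        F[ia, 2] += gBz + gCz
    return E


@njit(cache=True)
def area_kernel(pos, tri, k_A, A0, F):              # pragma: no cover
    """Global surface-area constraint force; returns the current area."""
    T = tri.shape[0]
    A = 0.0
    nx = np.empty(T)
    ny = np.empty(T)
    nz = np.empty(T)
    nn = np.empty(T)
    for t in range(T):
        ia, ib, ic = tri[t, 0], tri[t, 1], tri[t, 2]
        ux = pos[ib, 0] - pos[ia, 0]
        uy = pos[ib, 1] - pos[ia, 1]
        uz = pos[ib, 2] - pos[ia, 2]
        vx = pos[ic, 0] - pos[ia, 0]
        vy = pos[ic, 1] - pos[ia, 1]
        vz = pos[ic, 2] - pos[ia, 2]
        nx[t] = uy * vz - uz * vy
        ny[t] = uz * vx - ux * vz
        nz[t] = ux * vy - uy * vx
        nn[t] = math.sqrt(nx[t] ** 2 + ny[t] ** 2 + nz[t] ** 2)
        A += 0.5 * nn[t]
    lam = k_A * (A - A0) / A0
    for t in range(T):
        ia, ib, ic = tri[t, 0], tri[t, 1], tri[t, 2]
        s = lam * 0.5 / nn[t]
        qx = s * nx[t]
        qy = s * ny[t]
        qz = s * nz[t]
        ux = pos[ib, 0] - pos[ia, 0]
        uy = pos[ib, 1] - pos[ia, 1]
        uz = pos[ib, 2] - pos[ia, 2]
        vx = pos[ic, 0] - pos[ia, 0]
        vy = pos[ic, 1] - pos[ia, 1]
        vz = pos[ic, 2] - pos[ia, 2]
        gBx = vy * qz - vz * qy
        gBy = vz * qx - vx * qz
        gBz = vx * qy - vy * qx
        gCx = qy * uz - qz * uy
        gCy = qz * ux - qx * uz
        gCz = qx * uy - qy * ux
        F[ib, 0] -= gBx
        F[ib, 1] -= gBy
        F[ib, 2] -= gBz
        F[ic, 0] -= gCx
        F[ic, 1] -= gCy
        F[ic, 2] -= gCz
        F[ia, 0] += gBx + gCx
        F[ia, 1] += gBy + gCy
        F[ia, 2] += gBz + gCz
    return A
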