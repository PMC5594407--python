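"""Dynamic-programming search over monotone reparameterizations.

The elastic matching of two square-root velocity functions minimizes

    E(gamma) = Int |q1(t) - q2(gamma(t)) sqrt(gamma_dot(t))|^2 dt

over orientation-preserving diffeomorphisms gamma of [0, 1].  On a T x T
grid this is approximated by the cheapest strictly monotone lattice path
from (0, 0) to (T-1, T-1), where the edge from (i - di, j - dj) to (i, j)
represents a linear gamma segment of slope dj/di and contributes the
Riemann-sum cost of the integrand over its di parameter samples.

Two search modes are provided:

* :func:`dp_reparam` — numba-compiled DP over a bounded step neighborhood
  (all coprime steps with components <= 6); fast enough for routine use.
* :func:`dp_reparam_full` — exact DP over *all* monotone predecessor edges
  (O(T^4)); used on small grids to validate the bounded search, and itself
  checkable against brute-force path enumeration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dp_reparam", "dp_reparam_full", "edge_cost", "path_to_gamma"]

# coprime steps with components up to 6: slopes from 1/6 to 6 with
# intermediate rationals (5/6, 4/5, ...) so that near-identity warps are
# represented without coarse slope alternation
_STEPS = np.array(
    sorted({(p_, q_) for p_ in range(1, 7) for q_ in range(1, 7)
            if np.gcd(p_, q_) == 1}),
    dtype=np.int64,
)


def edge_cost(q1: np.ndarray, q2: np.ndarray, pi: int, pj: int, i: int, j: int,
              dt: float) -> float:
    """Cost of the monotone lattice edge (pi, pj) -> (i, j).

    Reference (pure python) implementation shared by the exact DP and the
    test-suite's brute-force path enumeration; the numba kernel inlines the
    identical arithmetic.
    """
    T = q1.shape[0]
    di, dj = i - pi, j - pj
    m = dj / di
    sq = np.sqrt(m)
    c = 0.0
    for s in range(1, di + 1):
        ti = pi + s
        tj = pj + s * m
        j0 = min(int(tj), T - 2)
        w = tj - j0
        v = (1.0 - w) * q2[j0] + w * q2[j0 + 1]
        e = q1[ti] - sq * v
        c += float(e @ e) * dt
    return c


@njit(cache=False)
def _dp_kernel(q1, q2, dt, di_arr, dj_arr):  # pragma: no cover - numba
    T = q1.shape[0]
    INF = 1e30
    D = np.full((T, T), INF)
    back = np.full((T, T), -1, dtype=np.int64)
    e0 = q1[0, 0] - q2[0, 0]
    e1 = q1[0, 1] - q2[0, 1]
    D[0, 0] = (e0 * e0 + e1 * e1) * dt
    nsteps = di_arr.shape[0]
    for i in range(1, T):
        for j in range(1, T):
            best = INF
            bs = -1
            for s in range(nsteps):
                di = di_arr[s]
                dj = dj_arr[s]
                pi = i - di
                pj = j - dj
                if pi < 0 or pj < 0:
                    continue
                base = D[pi, pj]
                if base >= INF:
                    continue
                m = dj / di
                sq = np.sqrt(m)
                c = 0.0
                for ss in range(1, di + 1):
                    ti = pi + ss
                    tj = pj + ss * m
                    j0 = int(tj)
                    if j0 > T - 2:
                        j0 = T - 2
                    w = tj - j0
                    v0 = (1.0 - w) * q2[j0, 0] + w * q2[j0 + 1, 0]
                    v1 = (1.0 - w) * q2[j0, 1] + w * q2[j0 + 1, 1]
                    a = q1[ti, 0] - sq * v0
                    b = q1[ti, 1] - sq * v1
                    c += (a * a + b * b) * dt
                tot = base + c
                if tot < best:
                    best = tot
                    bs = s
            D[i, j] = best
            back[i, j] = bs
    return D, back


def path_to_gamma(path_i: np.ndarray, path_j: np.ndarray, T: int) -> np.ndarray:
    """Piecewise-linear gamma sampled on the full uniform grid."""
    gamma = np.interp(np.arange(T), path_i, path_j) / (T - 1)
    gamma[0], gamma[-1] = 0.0, 1.0
    return gamma


def dp_reparam(q1: np.ndarray, q2: np.ndarray) -> tuple[np.ndarray, float]:
    """Best bounded-step reparameterization of q2 toward q1.

    Returns (gamma, cost): gamma sampled on the uniform T-grid with
    gamma(0)=0, gamma(1)=1, nondecreasing.
    """
    T = q1.shape[0]
    dt = 1.0 / (T - 1)
    D, back = _dp_kernel(
        np.ascontiguousarray(q1, dtype=np.float64),
        np.ascontiguousarray(q2, dtype=np.float64),
        dt,
        _STEPS[:, 0].copy(),
        _STEPS[:, 1].copy(),
    )
    # backtrack
    pi, pj = T - 1, T - 1
    path = [(pi, pj)]
    while (pi, pj) != (0, 0):
        s = back[pi, pj]
        if s < 0:
            raise RuntimeError("DP backtrack failed")  # unreachable: (1,1) step
        pi -= int(_STEPS[s, 0])
        pj -= int(_STEPS[s, 1])
        path.append((pi, pj))
    path.reverse()
    pi_arr = np.array([p[0] for p in path], dtype=float)
    pj_arr = np.array([p[1] for p in path], dtype=float)
    return path_to_gamma(pi_arr, pj_arr, T), float(D[T - 1, T - 1])


def dp_reparam_full(q1: np.ndarray, q2: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact DP over every monotone predecessor edge (small T only)."""
    T = q1.shape[0]
    dt = 1.0 / (T - 1)
    INF = np.inf
    D = np.full((T, T), INF)
    prev = {}
    d0 = q1[0] - q2[0]
    D[0, 0] = float(d0 @ d0) * dt
    for i in range(1, T):
        for j in range(1, T):
            best, barg = INF, None
            for pi in range(i):
                for pj in range(j):
                    if not np.isfinite(D[pi, pj]):
                        continue
                    tot = D[pi, pj] + edge_cost(q1, q2, pi, pj, i, j, dt)
                    if tot < best:
                        best, barg = tot, (pi, pj)
            D[i, j] = best
            prev[(i, j)] = barg
    node = (T - 1, T - 1)
    path = [node]
    while node != (0, 0):
        node = prev[node]
        path.append(node)
    path.reverse()
    pi_arr = np.array([p[0] for p in path], dtype=float)
    pj_arr = np.array([p[1] for p in path], dtype=float)
    return path_to_gamma(pi_arr, pj_arr, T), float(D[T - 1, T - 1])
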