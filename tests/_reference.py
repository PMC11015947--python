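"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive (python loops, full sorts) and shares
no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def _dist(p, q) -> float:
    # same elementary distance as the package (np.hypot): the oracle tests
    # the algorithm and tie rule, not the libm rounding of hypot
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def brute_knn_mean(points: np.ndarray, k: int) -> float:
    """Mean kth-NN distance by full O(n^2) pairwise sort."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    total = 0.0
    for i in range(n):
        d = sorted(_dist(pts[i], pts[j]) for j in range(n) if j != i)
        total += d[k - 1]
    return total / n


def point_in_ring(x: float, y: float, ring: np.ndarray) -> bool:
    """Even-odd ray-crossing test (boundary treatment unspecified)."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def brute_optics(points: np.ndarray, min_pts: int, max_eps: float = math.inf):
    """Naive OPTICS (Ankerst et al. 1999) with the package's tie rule:
    visit the unprocessed point with smallest reachability, ties broken by
    ascending input index; component seeds keep reachability +inf.

    Returns (ordering, reachability, core_distances) as plain lists/arrays.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dist = [[_dist(pts[i], pts[j]) for j in range(n)] for i in range(n)]
    core = []
    for i in range(n):
        others = sorted(dist[i][j] for j in range(n) if j != i)
        c = others[min_pts - 2]  # (min_pts-1)th other point
        core.append(c if c <= max_eps else math.inf)

    reach = [math.inf] * n
    processed = [False] * n
    order = []
    while len(order) < n:
        best, best_r = None, math.inf
        for i in range(n):
            if not processed[i] and reach[i] < best_r:
                best, best_r = i, reach[i]
        if best is None:  # new component: lowest-index unprocessed
            best = next(i for i in range(n) if not processed[i])
        order.append(best)
        processed[best] = True
        if math.isfinite(core[best]):
            for q in range(n):
                if processed[q] or dist[best][q] > max_eps:
                    continue
                new_r = max(core[best], dist[best][q])
                if new_r < reach[q]:
                    reach[q] = new_r
    return np.array(order), np.array(reach), np.array(core)
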