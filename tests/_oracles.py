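"""Independent brute-force oracles used by the test suite.

Kept deliberately naive and separate from the package implementation:
the Delaunay oracle enumerates all point triples and tests the
empty-circumcircle property directly (O(n^4)); the package path goes
through scipy's Qhull triangulation instead.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_delaunay_edges(xy: np.ndarray, eps: float = 1e-9) -> set[tuple[int, int]]:
    """Edges of the Delaunay triangulation by circumcircle enumeration.

    For every triple of points, compute the circumcircle; if no other
    point lies strictly inside it, the triple is a Delaunay triangle
    and its three edges are Delaunay edges.  Assumes points in general
    position (continuous random coordinates).
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    edges: set[tuple[int, int]] = set()
    idx = np.arange(n)
    for i, j, k in itertools.combinations(range(n), 3):
        ax, ay = xy[i]
        bx, by = xy[j]
        cx, cy = xy[k]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:        # collinear triple: no circumcircle
            continue
        a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
        ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
        uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        others = idx[(idx != i) & (idx != j) & (idx != k)]
        d2 = (xy[others, 0] - ux) ** 2 + (xy[others, 1] - uy) ** 2
        if np.all(d2 > r2 - eps):
            edges.add((i, j))
            edges.add((i, k))
            edges.add((j, k))
    return edges


def brute_force_pruned_edges(xy: np.ndarray, delta: float) -> set[tuple[int, int]]:
    """Delaunay edges with Euclidean length <= delta (inclusive)."""
    xy = np.asarray(xy, dtype=float)
    out = set()
    for i, j in brute_force_delaunay_edges(xy):
        if np.hypot(*(xy[i] - xy[j])) <= delta:
            out.add((i, j))
    return out
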