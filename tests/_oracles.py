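"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised estimation paths: K is
accumulated by a naive double loop over ordered pairs (sharing only the
single-pair edge-weight routine), so any indexing or vectorisation defect
in the fast path shows up as a mismatch.
"""

import numpy as np

from mifspat.geometry import Window, edge_weight


def naive_k_univariate(points, window: Window, r_grid, correction: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    grid = np.atleast_1d(np.asarray(r_grid, dtype=float))
    acc = np.zeros(len(grid))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.hypot(*(pts[j] - pts[i])))
            hits = d < grid
            if hits.any():
                acc[hits] += min(edge_weight(pts[i], pts[j], window, correction), n)
    return window.area * acc / (n * (n - 1))


def naive_k_bivariate(anchors, others, window: Window, r_grid, correction: str) -> np.ndarray:
    a = np.asarray(anchors, dtype=float)
    b = np.asarray(others, dtype=float)
    cap = len(a) + len(b)
    grid = np.atleast_1d(np.asarray(r_grid, dtype=float))
    acc = np.zeros(len(grid))
    for i in range(len(a)):
        for j in range(len(b)):
            d = float(np.hypot(*(b[j] - a[i])))
            hits = d < grid
            if hits.any():
                acc[hits] += min(edge_weight(a[i], b[j], window, correction), cap)
    return window.area * acc / (len(a) * len(b))


def uniform_points_in(rng: np.random.Generator, window: Window, n: int) -> np.ndarray:
    lo = window.vertices.min(axis=0)
    hi = window.vertices.max(axis=0)
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.uniform(lo, hi, size=(4 * n + 16, 2))
        pts = np.vstack([pts, cand[window.contains(cand)]])
    return pts[:n]


def random_convex_window(rng: np.random.Generator, scale: float = 100.0) -> Window:
    from mifspat.geometry import convex_hull_window

    while True:
        pts = rng.uniform(0, scale, size=(rng.integers(4, 10), 2))
        try:
            return convex_hull_window(pts)
        except Exception:
            continue
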