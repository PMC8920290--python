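"""Observation windows and edge-correction weights for planar point patterns.

The observation region of a tissue sample is taken to be the convex hull of
all measured cells.  Edge-correction weights compensate for neighbours lost
outside the window:

* ``translation``: w_ij = |W| / |W ∩ (W + (p_j − p_i))|, the reciprocal
  fraction of translations of the pair that keep both ends inside W.
* ``isotropic``: w_ij = reciprocal of the fraction of the circle centred at
  p_i with radius d(p_i, p_j) whose circumference lies inside W, computed
  exactly for convex polygons by clipping arcs against each edge half-plane.

Both weights are ≥ 1 and equal 1 for interior pairs.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateWindowError, PointOutsideWindowError

CORRECTIONS = ("translation", "isotropic", "none")

_TWO_PI = 2.0 * np.pi


class Window:
    """A convex polygonal observation window in micron coordinates.

    Vertices are stored counter-clockwise without repetition of the first
    vertex.  Construction validates convexity and positive area.
    """

    def __init__(self, vertices) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DegenerateWindowError("a window needs at least 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise DegenerateWindowError("window vertices must be finite")
        area2 = _signed_area2(v)
        if area2 < 0:  # clockwise input: flip orientation
            v = v[::-1]
            area2 = -area2
        if area2 <= 0:
            raise DegenerateWindowError("window vertices are collinear (zero area)")
        edges = np.roll(v, -1, axis=0) - v
        cross = edges[:, 0] * np.roll(edges, -1, axis=0)[:, 1] - edges[:, 1] * np.roll(edges, -1, axis=0)[:, 0]
        scale = float(np.abs(edges).max()) ** 2
        if np.any(cross < -1e-9 * scale):
            raise DegenerateWindowError("window polygon is not convex")
        self.vertices = v
        self._edges = edges
        lengths = np.hypot(edges[:, 0], edges[:, 1])
        if np.any(lengths == 0):
            keep = lengths > 0
            self.vertices = v = v[keep]
            self._edges = edges = np.roll(v, -1, axis=0) - v
            lengths = np.hypot(edges[:, 0], edges[:, 1])
        # inward unit normals (interior lies left of each CCW edge)
        self._n_in = np.column_stack((-edges[:, 1], edges[:, 0])) / lengths[:, None]
        # polar angle of each outward normal, used for arc clipping
        self._theta_out = np.arctan2(-self._n_in[:, 1], -self._n_in[:, 0])
        self._shapely = shapely.polygons(self.vertices)

    @property
    def area(self) -> float:
        """Window area |W| in µm² (shoelace formula)."""
        return 0.5 * _signed_area2(self.vertices)

    @property
    def diameter(self) -> float:
        """Largest vertex-to-vertex distance."""
        d = self.vertices[:, None, :] - self.vertices[None, :, :]
        return float(np.sqrt((d**2).sum(axis=2)).max())

    def as_shapely(self) -> shapely.Polygon:
        return self._shapely

    def contains(self, points, tol: float = 1e-6) -> np.ndarray:
        """Boolean mask of points inside (or on the boundary of) the window."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        # signed distance to each edge line, positive inside
        h = self.signed_edge_distances(p)
        return (h >= -tol).all(axis=1)

    def signed_edge_distances(self, points: np.ndarray) -> np.ndarray:
        """(n_points, n_edges) perpendicular distances, positive inside."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        rel = p[:, None, :] - self.vertices[None, :, :]
        return np.einsum("pek,ek->pe", rel, self._n_in)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Window({len(self.vertices)} vertices, area={self.area:.1f} µm²)"


def _signed_area2(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rectangle_window(width: float, height: float, origin=(0.0, 0.0)) -> Window:
    """Axis-aligned rectangular window of the given size."""
    x0, y0 = origin
    return Window([(x0, y0), (x0 + width, y0), (x0 + width, y0 + height), (x0, y0 + height)])


def convex_hull_window(points) -> Window:
    """Convex hull of all cell locations of a sample, as the observation window.

    The hull is computed on every measured cell (any marker status): the
    tissue region is defined by where cells could be observed at all, not by
    where the positive cells happen to lie.

    Raises
    ------
    DegenerateWindowError
        For fewer than 3 points or a collinear configuration.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise DegenerateWindowError("convex hull needs at least 3 points")
    try:
        hull = ConvexHull(p)
    except QhullError as exc:
        raise DegenerateWindowError(f"degenerate point configuration: {exc}") from exc
    return Window(p[hull.vertices])  # ConvexHull returns CCW order in 2-D


# ---------------------------------------------------------------------------
# edge-correction weights
# ---------------------------------------------------------------------------


def translation_weights(displacements, window: Window) -> np.ndarray:
    """Translation-correction weights for an array of pair displacements.

    w = |W| / |W ∩ (W + v)| for each displacement v = p_j − p_i.  Symmetric
    in ±v, so one evaluation per unordered pair suffices.
    """
    v = np.atleast_2d(np.asarray(displacements, dtype=float))
    shifted = shapely.polygons(window.vertices[None, :, :] + v[:, None, :])
    areas = shapely.area(shapely.intersection(window.as_shapely(), shifted))
    return window.area / areas


def isotropic_weights(centers, radii, window: Window) -> np.ndarray:
    """Ripley's isotropic-correction weights for circles (center, radius).

    For each circle, the weight is the reciprocal of the fraction of its
    circumference lying inside the convex window, obtained by removing the
    arc excluded by every window edge whose line cuts the circle and
    measuring the union of the excluded arcs exactly.
    """
    c = np.atleast_2d(np.asarray(centers, dtype=float))
    d = np.atleast_1d(np.asarray(radii, dtype=float))
    h = window.signed_edge_distances(c)  # (P, E), positive inside
    w = np.ones(len(c))
    cut = h < d[:, None]  # edges whose line intersects the circle
    needs = cut.any(axis=1) & (d > 0)
    if not np.any(needs):
        return w
    theta = window._theta_out
    for p in np.flatnonzero(needs):
        ratio = np.clip(h[p, cut[p]] / d[p], -1.0, 1.0)
        alpha = np.arccos(ratio)  # half-width of each excluded arc
        excluded = _union_measure_circular(theta[cut[p]], alpha)
        frac = 1.0 - excluded / _TWO_PI
        if frac <= 0:
            w[p] = np.inf  # caller caps; circle circumference fully outside
        else:
            w[p] = 1.0 / frac
    return w


def _union_measure_circular(centers: np.ndarray, half_widths: np.ndarray) -> float:
    """Total measure of a union of arcs [c−a, c+a] on the circle [0, 2π)."""
    lo = (centers - half_widths) % _TWO_PI
    hi = lo + 2.0 * half_widths  # may exceed 2π (wraps)
    intervals = []
    for a, b in zip(lo, hi):
        if b > _TWO_PI:
            intervals.append((a, _TWO_PI))
            intervals.append((0.0, b - _TWO_PI))
        else:
            intervals.append((a, b))
    intervals.sort()
    total = 0.0
    cur_lo, cur_hi = intervals[0]
    for a, b in intervals[1:]:
        if a > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = a, b
        else:
            cur_hi = max(cur_hi, b)
    total += cur_hi - cur_lo
    return total


def edge_weight(p_i, p_j, window: Window, correction: str) -> float:
    """Edge-correction weight for a single ordered pair of points.

    The anchor ``p_i`` is the ring centre: for the isotropic correction the
    circle of radius d(p_i, p_j) is drawn about ``p_i``.  The translation
    weight depends only on the displacement and is symmetric.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    inside = window.contains(np.vstack([p_i, p_j]))
    if not inside.all():
        raise PointOutsideWindowError("both points must lie inside the window")
    if correction == "none":
        return 1.0
    if correction == "translation":
        return float(translation_weights(p_j - p_i, window)[0])
    d = float(np.hypot(*(p_j - p_i)))
    return float(isotropic_weights(p_i, d, window)[0])
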