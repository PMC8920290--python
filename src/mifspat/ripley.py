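"""Ripley's K estimation for univariate and bivariate (cross-type) patterns.

The univariate estimator over a convex window W with area A is

    K̂(r) = A / (n(n−1)) · Σ_i Σ_{j≠i} w_ij · 1{d(p_i, p_j) < r}

with w_ij ≥ 1 an edge-correction weight (``translation``, ``isotropic`` or
``none``).  Under complete spatial randomness E[K̂(r)] = πr².  The bivariate
(cross) form replaces the double sum over one pattern by a sum over ordered
(anchor, other) pairs and normalises by n1·n2; the anchor is the ring
centre, so the isotropic weight uses the circle drawn about the anchor.

The indicator is strict (d < r): pairs at exactly distance r do not count.
Directional weights are capped at the number of points in the pattern as a
guard against near-zero boundary arc fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import NotEstimableError, PointOutsideWindowError
from .geometry import CORRECTIONS, Window, isotropic_weights, translation_weights

__all__ = ["KEstimate", "ripley_k_univariate", "ripley_k_bivariate", "theoretical_csr"]


@dataclass(frozen=True)
class KEstimate:
    """Ripley's K evaluated on an ascending radius grid.

    ``n`` is the point count for a univariate estimate or the (n1, n2)
    anchor/other pair for a bivariate estimate.
    """

    r_grid: np.ndarray
    k_values: np.ndarray
    correction: str
    n: int | tuple[int, int]
    window_area: float

    def k_at(self, r: float) -> float:
        """K̂ at a radius that must lie on the grid."""
        idx = np.flatnonzero(np.isclose(self.r_grid, r))
        if idx.size == 0:
            raise ValueError(f"radius {r} not on the estimate's grid")
        return float(self.k_values[idx[0]])


def _as_grid(r_grid) -> np.ndarray:
    r = np.atleast_1d(np.asarray(r_grid, dtype=float))
    if r.size == 0 or np.any(~np.isfinite(r)) or np.any(r < 0):
        raise ValueError("r_grid must be finite and non-negative")
    if np.any(np.diff(r) < 0):
        raise ValueError("r_grid must be ascending")
    return r


def _check_inside(points: np.ndarray, window: Window) -> None:
    if not window.contains(points).all():
        raise PointOutsideWindowError("all points must lie inside the window")


def _pair_weight_sums(
    coords_i: np.ndarray,
    coords_j: np.ndarray,
    window: Window,
    correction: str,
    cap: float,
    both_directions: bool,
) -> np.ndarray:
    """Per-pair weight contribution; w_ij + w_ji if ``both_directions``."""
    if len(coords_i) == 0:
        return np.zeros(0)
    if correction == "none":
        w = np.ones(len(coords_i))
        return 2.0 * w if both_directions else w
    if correction == "translation":
        w = np.minimum(translation_weights(coords_j - coords_i, window), cap)
        return 2.0 * w if both_directions else w
    d = np.hypot(*(coords_j - coords_i).T)
    w = np.minimum(isotropic_weights(coords_i, d, window), cap)
    if both_directions:
        w = w + np.minimum(isotropic_weights(coords_j, d, window), cap)
    return w


def ripley_k_univariate(points, window: Window, r_grid, correction: str = "translation") -> KEstimate:
    """Edge-corrected Ripley's K of one point pattern.

    Raises
    ------
    NotEstimableError
        For n < 2, where the n(n−1) normalisation is undefined.  This is a
        distinct outcome from K̂ = 0 (points present but none within r).
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    p = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(p)
    if n < 2:
        raise NotEstimableError("univariate Ripley's K needs at least 2 points")
    _check_inside(p, window)
    r = _as_grid(r_grid)
    r_max = float(r.max())
    tree = cKDTree(p)
    pairs = tree.query_pairs(r_max, output_type="ndarray")  # unordered, i < j
    d = np.hypot(*(p[pairs[:, 1]] - p[pairs[:, 0]]).T) if len(pairs) else np.zeros(0)
    strict = d < r_max
    pairs, d = pairs[strict], d[strict]
    wsum = _pair_weight_sums(p[pairs[:, 0]], p[pairs[:, 1]], window, correction, cap=n, both_directions=True)
    scale = window.area / (n * (n - 1))
    k = np.array([scale * wsum[d < ri].sum() for ri in r])
    return KEstimate(r_grid=r, k_values=k, correction=correction, n=n, window_area=window.area)


def ripley_k_bivariate(
    anchor_points, other_points, window: Window, r_grid, correction: str = "translation"
) -> KEstimate:
    """Bivariate (cross) Ripley's K counting other-type cells around anchors.

    K̂₁₂(r) = A/(n1·n2) · Σ_{i∈anchors} Σ_{j∈others} w_ij · 1{d < r}.  The
    statistic is asymmetric under the isotropic correction (rings are drawn
    about anchors) and exactly symmetric under the translation correction.

    Raises
    ------
    NotEstimableError
        If either point set is empty.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    a = np.atleast_2d(np.asarray(anchor_points, dtype=float))
    b = np.atleast_2d(np.asarray(other_points, dtype=float))
    if a.size == 0 or b.size == 0:
        raise NotEstimableError("bivariate Ripley's K needs ≥1 anchor and ≥1 other cell")
    n1, n2 = len(a), len(b)
    _check_inside(a, window)
    _check_inside(b, window)
    r = _as_grid(r_grid)
    r_max = float(r.max())
    neighbours = cKDTree(a).query_ball_tree(cKDTree(b), r_max)
    ai = np.repeat(np.arange(n1), [len(nb) for nb in neighbours])
    bj = np.fromiter((j for nb in neighbours for j in nb), dtype=np.intp, count=len(ai))
    d = np.hypot(*(a[ai] - b[bj]).T) if len(ai) else np.zeros(0)
    strict = d < r_max
    ai, bj, d = ai[strict], bj[strict], d[strict]
    w = _pair_weight_sums(a[ai], b[bj], window, correction, cap=n1 + n2, both_directions=False)
    scale = window.area / (n1 * n2)
    k = np.array([scale * w[d < ri].sum() for ri in r])
    return KEstimate(r_grid=r, k_values=k, correction=correction, n=(n1, n2), window_area=window.area)


def theoretical_csr(r_grid) -> np.ndarray:
    """Theoretical K under complete spatial randomness: πr² per radius."""
    r = _as_grid(r_grid)
    return np.pi * r**2
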