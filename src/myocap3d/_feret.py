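"""Minimal/maximal Feret (caliper) widths of planar point sets.

The minimal Feret diameter of a convex region equals the minimum over
orientations of the width of its projection. For a convex polygon the minimum
is attained with one caliper flush against an edge, so it suffices to scan
hull edges (rotating calipers); an exhaustive angle sweep is provided as an
independent oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull

from .errors import DegenerateGeometryError

__all__ = ["min_feret_points", "max_feret_points", "feret_width_sweep"]


def _hull_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise DegenerateGeometryError("need at least two 2D points")
    if len(np.unique(pts, axis=0)) < 3:
        return np.unique(pts, axis=0)
    try:
        hull = ConvexHull(pts)
    except Exception:  # collinear input
        return np.unique(pts, axis=0)
    return pts[hull.vertices]


def min_feret_points(points: np.ndarray) -> float:
    """Minimal Feret diameter of a 2D point set (rotating calipers on the hull)."""
    hp = _hull_points(points)
    if len(hp) < 3:
        return 0.0
    best = np.inf
    n = len(hp)
    for i in range(n):
        edge = hp[(i + 1) % n] - hp[i]
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = np.abs((hp - hp[i]) @ normal).max()
        best = min(best, width)
    return float(best)


def max_feret_points(points: np.ndarray) -> float:
    """Maximal Feret diameter (largest pairwise distance on the hull)."""
    hp = _hull_points(points)
    if len(hp) < 2:
        return 0.0
    d = np.linalg.norm(hp[:, None, :] - hp[None, :, :], axis=-1)
    return float(d.max())


def feret_width_sweep(points: np.ndarray, step_deg: float = 1.0) -> float:
    """Brute-force minimal projection width over an exhaustive angle grid.

    Oracle for :func:`min_feret_points`; O(n·angles), used in tests only.
    """
    pts = np.asarray(points, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    normals = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ normals.T  # (n_points, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())
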