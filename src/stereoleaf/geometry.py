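"""Small planar-geometry helpers shared by the trait and overlap modules.

Everything operates on ``(row, col)`` float arrays of shape ``(n, 2)`` unless
noted.  Polygons are implicitly closed (last vertex connects to first).
"""

from __future__ import annotations

import numpy as np


def polygon_length(vertices: np.ndarray, closed: bool = True) -> float:
    """Total edge length of a polyline / polygon."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 2:
        return 0.0
    seg = np.diff(v, axis=0)
    total = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if closed:
        total += float(np.hypot(*(v[0] - v[-1])))
    return total


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 1], v[:, 0]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def signed_polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area with sign; positive when (col, row) vertices run CCW."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 1], v[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def points_to_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to the segment ``a``-``b``."""
    p = np.asarray(points, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(*(p - a).T)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(p - proj).T)


def points_to_line_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distance from each point to the infinite line through a, b."""
    p = np.asarray(points, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    norm = float(np.hypot(*ab))
    if norm == 0.0:
        return np.hypot(*(p - a).T)
    # 2-D cross product magnitude / |ab|
    return np.abs((p[:, 0] - a[0]) * ab[1] - (p[:, 1] - a[1]) * ab[0]) / norm


def points_to_polygon_boundary_distance(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest edge of a closed polygon."""
    p = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    n = len(poly)
    best = np.full(len(p), np.inf)
    for i in range(n):
        d = points_to_segment_distance(p, poly[i], poly[(i + 1) % n])
        np.minimum(best, d, out=best)
    return best


def rotation_angle_to_down(p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle (radians) of the vector p1->p2 measured from the +row (down) axis.

    Rotating the plane by the negative of this angle about ``p1`` makes the
    vector point straight down.
    """
    v = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    return float(np.arctan2(v[1], v[0]))
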