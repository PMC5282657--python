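"""Separation of overlapped round leaves by concave-point contour splitting.

Round rape leaves are approximately elliptical, so an overlapped clump can
be recovered from its outline alone: simplify the outline (Douglas-Peucker)
to suppress pixel-level roughness, find the concave vertices (interior angle
above 180 degrees — these occur where two leaf boundaries cross), cut the
full-resolution contour at those points, and fit one ellipse per arc.  The
method is only meaningful for round-leaf morphology; deeply serrated leaves
produce concave points everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import EllipseModel

from stereoleaf.geometry import signed_polygon_area


@dataclass
class PolygonalContour:
    vertices: np.ndarray  # (n, 2) row, col
    tolerance: float


@dataclass
class RecoveredLeaf:
    ellipse: tuple          # ((row, col), a, b, angle_rad), a >= b
    support_arc: np.ndarray  # contour points the fit used
    mask: np.ndarray | None = None


def approximate_polygon(contour: np.ndarray, tolerance: float = 3.0) -> PolygonalContour:
    """Douglas-Peucker simplification with maximum deviation ``tolerance``."""
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise ValueError("contour needs at least 3 points")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # Douglas-Peucker always keeps the first vertex; start the ring at the
    # point farthest from the centroid, which lies on the true outline
    start = int(np.argmax(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    ring = np.roll(pts, -start, axis=0)
    ring = np.vstack([ring, ring[:1]])
    simplified = measure.approximate_polygon(ring, tolerance)
    if len(simplified) > 1 and np.allclose(simplified[0], simplified[-1]):
        simplified = simplified[:-1]
    # drop zero-length edges
    keep = np.ones(len(simplified), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(simplified, axis=0), axis=1) > 1e-9
    return PolygonalContour(simplified[keep], float(tolerance))


def detect_concave_points(poly: PolygonalContour) -> np.ndarray:
    """Vertices whose interior angle exceeds 180 degrees, in contour order.

    Uses the cross-product sign at each vertex against the polygon's overall
    orientation, so the result is independent of winding direction.
    """
    v = np.asarray(poly.vertices, dtype=float)
    n = len(v)
    if n < 4:
        return np.empty((0, 2))
    orientation = np.sign(signed_polygon_area(v))
    prev = np.roll(v, 1, axis=0)
    nxt = np.roll(v, -1, axis=0)
    e1 = v - prev
    e2 = nxt - v
    cross = e1[:, 1] * e2[:, 0] - e1[:, 0] * e2[:, 1]
    concave = np.sign(cross) == -orientation
    return v[concave]


def _fit_arc_ellipse(arc: np.ndarray):
    if len(arc) < 5:
        return None
    model = EllipseModel.from_estimate(arc[:, ::-1])
    if not model:
        return None
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = float(model.theta)
    if not (np.isfinite(a) and np.isfinite(b)) or min(a, b) <= 0:
        return None
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    if a > 10 * max(np.ptp(arc[:, 0]), np.ptp(arc[:, 1])):
        return None  # wildly extrapolated fit from a near-straight arc
    return ((yc, xc), float(a), float(b), float(theta))


def segment_and_fit(poly: PolygonalContour, concave: np.ndarray,
                    full_contour: np.ndarray, min_arc_frac: float = 0.10,
                    merge_overlap: float = 0.80,
                    image_shape: tuple | None = None) -> list[RecoveredLeaf]:
    """Cut the contour at the concave points and fit one ellipse per arc.

    Arcs shorter than ``min_arc_frac`` of the contour are merged with their
    following neighbor before fitting; fitted ellipses overlapping another by
    more than ``merge_overlap`` (area of intersection over the smaller area)
    are collapsed to the one with the longer support arc.  With fewer than
    two concave points the whole contour is treated as a single leaf.
    """
    pts = np.asarray(full_contour, dtype=float)
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    n = len(pts)

    if len(concave) < 2:
        fit = _fit_arc_ellipse(pts)
        if fit is None:
            return []
        return [RecoveredLeaf(fit, pts, _raster(fit, image_shape))]

    # indices on the full contour nearest each concave point
    cut_idx = sorted({int(np.argmin(np.linalg.norm(pts - c, axis=1)))
                      for c in np.asarray(concave, dtype=float)})
    arcs = []
    for k in range(len(cut_idx)):
        i, j = cut_idx[k], cut_idx[(k + 1) % len(cut_idx)]
        idx = np.arange(i, j + 1) if j > i else np.concatenate(
            [np.arange(i, n), np.arange(0, j + 1)])
        arcs.append(pts[idx])

    # merge short arcs into the next one
    min_len = min_arc_frac * n
    merged, carry = [], None
    for arc in arcs:
        if carry is not None:
            arc = np.vstack([carry, arc])
            carry = None
        if len(arc) < min_len:
            carry = arc
        else:
            merged.append(arc)
    if carry is not None:
        if merged:
            merged[0] = np.vstack([carry, merged[0]])
        else:
            merged = [carry]

    leaves = []
    for arc in merged:
        fit = _fit_arc_ellipse(arc)
        if fit is None:
            continue
        leaves.append(RecoveredLeaf(fit, arc, _raster(fit, image_shape)))

    return _merge_duplicates(leaves, merge_overlap, image_shape)


def _raster(ellipse, image_shape):
    if image_shape is None:
        return None
    (r0, c0), a, b, theta = ellipse
    mask = np.zeros(image_shape, dtype=bool)
    rr, cc = draw_ellipse(r0, c0, b, a, shape=image_shape, rotation=-theta)
    mask[rr, cc] = True
    return mask


def _merge_duplicates(leaves, merge_overlap, image_shape):
    if len(leaves) < 2:
        return leaves
    # rasterize on a common canvas large enough for all ellipses
    if image_shape is None:
        hi = max(int(le.ellipse[0][0] + le.ellipse[1]) + 2 for le in leaves)
        wi = max(int(le.ellipse[0][1] + le.ellipse[1]) + 2 for le in leaves)
        shape = (max(hi, 1), max(wi, 1))
    else:
        shape = image_shape
    masks = [_raster(le.ellipse, shape) for le in leaves]
    order = np.argsort([-len(le.support_arc) for le in leaves])
    kept, kept_masks = [], []
    for i in order:
        duplicate = False
        for m in kept_masks:
            inter = (masks[i] & m).sum()
            denom = min(masks[i].sum(), m.sum())
            if denom > 0 and inter / denom > merge_overlap:
                duplicate = True
                break
        if not duplicate:
            kept.append(leaves[i])
            kept_masks.append(masks[i])
    kept.sort(key=lambda le: -len(le.support_arc))
    return kept


def split_overlapped_leaves(mask: np.ndarray, tolerance: float = 3.0,
                            min_arc_frac: float = 0.10) -> list[RecoveredLeaf]:
    """Convenience pipeline: contour -> simplify -> concave points -> fit."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("empty mask")
    contour = max(contours, key=len) - 1.0
    poly = approximate_polygon(contour, tolerance)
    concave = detect_concave_points(poly)
    return segment_and_fit(poly, concave, contour, min_arc_frac=min_arc_frac,
                           image_shape=mask.shape)
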