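"""Leaf foreground extraction from top-view RGB images.

Two entry paths:

* canopy level — :func:`segment_canopy` (normalized-green chromaticity
  threshold) followed by :func:`remove_stems_and_label` (morphological
  opening removes the slender stems, connected components become leaves);
* single leaf — :func:`rotate_petiole_down`, :func:`segment_leaf_exg_exr`
  (excess-green minus excess-red rule), :func:`remove_petiole` (bottom-up
  run-width scan) and :func:`finalize_leaf` (largest component, small-hole
  filling, contour tracing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform


class SegmentationError(ValueError):
    """Raised when an image cannot be segmented under the stated contract."""


@dataclass
class CanopyMask:
    """Canopy foreground after stem removal with per-leaf integer labels."""

    binary: np.ndarray
    labels: np.ndarray
    n_leaves: int


@dataclass
class PetioleAnnotation:
    """Two user-marked petiole points, ``(row, col)`` each.

    ``p1`` is the stem-leaf intersection; ``p2`` only fixes the direction in
    which the petiole leaves the blade.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError("petiole annotation points must differ")


@dataclass
class LeafShape:
    """A single leaf blade: mask, outer contour and interior cavity contours.

    Contours are sub-pixel ``(row, col)`` polygons in the coordinates of
    ``mask``; ``origin`` locates the crop inside its source image.
    """

    mask: np.ndarray
    outer_contour: np.ndarray
    cavities: list = field(default_factory=list)
    origin: tuple[int, int] = (0, 0)


@dataclass
class RotatedCrop:
    """Result of :func:`rotate_petiole_down`: the image plus the transform."""

    image: np.ndarray
    p1: tuple[float, float]
    angle_deg: float
    _matrix: np.ndarray = field(repr=False, default=None)

    def transform_point(self, point) -> np.ndarray:
        """Map a source-image ``(row, col)`` point into the rotated canvas."""
        r, c = point
        v = self._matrix @ np.array([r, c, 1.0])
        return v[:2]


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise SegmentationError("expected an RGB image of shape (h, w, 3)")
    return image.astype(float)


def segment_canopy(image: np.ndarray, g_threshold: float = 0.40,
                   brightness_floor: float = 20.0) -> np.ndarray:
    """Binary blade mask from normalized-RGB green chromaticity.

    A pixel is foreground iff g/(r+g+b) > ``g_threshold`` and the channel sum
    exceeds ``3 * brightness_floor`` (dark and zero-sum pixels stay
    background).
    """
    rgb = _as_rgb(image)
    total = rgb.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_chroma = np.where(total > 0, rgb[:, :, 1] / np.maximum(total, 1e-12), 0.0)
    return (g_chroma > g_threshold) & (total > 3.0 * brightness_floor)


def remove_stems_and_label(binary: np.ndarray, opening_radius: int = 5) -> CanopyMask:
    """Open with a disk to drop slender stems, then label leaves by size.

    8-connected components are labeled 1..n in decreasing pixel-area order.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise SegmentationError("empty foreground mask")
    opened = morphology.opening(binary, morphology.disk(opening_radius))
    if not opened.any():
        warnings.warn("all structure removed by opening; n_leaves = 0")
        return CanopyMask(opened, np.zeros_like(binary, dtype=int), 0)
    raw = measure.label(opened, connectivity=2)
    areas = np.bincount(raw.ravel())[1:]
    order = np.argsort(-areas, kind="stable") + 1
    labels = np.zeros_like(raw)
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return CanopyMask(opened, labels, len(order))


def segment_leaf_exg_exr(crop: np.ndarray) -> np.ndarray:
    """Foreground where excess green exceeds excess red: ExG - ExR > 0.

    With chromaticities r, g, b normalized to r+g+b = 1:
    ExG = 2g - r - b and ExR = 1.4r - g.
    """
    rgb = _as_rgb(crop)
    total = rgb.sum(axis=2)
    safe = np.maximum(total, 1e-12)
    r, g, b = (rgb[:, :, i] / safe for i in range(3))
    exg = 2.0 * g - r - b
    exr = 1.4 * r - g
    return (exg - exr > 0) & (total > 0)


def rotate_petiole_down(crop: np.ndarray, ann: PetioleAnnotation) -> RotatedCrop:
    """Rotate the crop about ``p1`` so the petiole vector p1->p2 points down.

    The canvas is expanded so that nothing is cropped; revealed pixels are
    black.  Returns the rotated image together with the affine map, so the
    annotation can be carried into the new frame.
    """
    image = _as_rgb(crop).astype(np.uint8)
    p1 = np.asarray(ann.p1, dtype=float)
    theta = _petiole_angle(p1, np.asarray(ann.p2, dtype=float))

    h, w = image.shape[:2]
    # rotation by -theta about p1, in (row, col) coordinates
    c, s = np.cos(-theta), np.sin(-theta)
    rot = np.array([[c, -s], [s, c]])
    corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], dtype=float)
    mapped = (corners - p1) @ rot.T + p1
    shift = np.floor(mapped.min(axis=0))
    out_shape = tuple(np.ceil(mapped.max(axis=0) - shift).astype(int) + 1)

    matrix = np.eye(3)
    matrix[:2, :2] = rot
    matrix[:2, 2] = p1 - rot @ p1 - shift
    inv = np.linalg.inv(matrix)

    def inverse_map(coords):
        return (coords @ inv[:2, :2].T) + inv[:2, 2]

    rotated = np.stack(
        [
            transform.warp(image[:, :, ch].astype(float), inverse_map,
                           output_shape=out_shape, order=1, cval=0.0)
            for ch in range(3)
        ],
        axis=2,
    )
    out = np.clip(np.round(rotated), 0, 255).astype(np.uint8)
    result = RotatedCrop(out, tuple(p1 - shift), float(np.degrees(theta)), matrix)
    return result


def _petiole_angle(p1: np.ndarray, p2: np.ndarray) -> float:
    v = p2 - p1
    if np.hypot(*v) == 0:
        raise ValueError("petiole points coincide")
    return float(np.arctan2(v[1], v[0]))


def remove_petiole(mask: np.ndarray, width_threshold: int = 25,
                   petiole_col: int | None = None) -> np.ndarray:
    """Strip the petiole by a bottom-up run-width scan.

    Starting from the bottom row, the contiguous foreground run containing
    the petiole column is cleared while its width stays strictly below
    ``width_threshold`` pixels; the scan stops at the first row whose run
    reaches the threshold (the blade shoulder).  The run is tracked upward by
    its center column, so a slightly tilted stalk is still followed.  The
    default threshold of 25 px suits the rig's native resolution.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    rows_any = np.flatnonzero(mask.any(axis=1))
    if rows_any.size == 0:
        raise SegmentationError("empty mask")
    col = petiole_col
    if col is None:
        bottom = rows_any[-1]
        col = int(np.median(np.flatnonzero(mask[bottom])))
    for row in range(rows_any[-1], rows_any[0] - 1, -1):
        line = mask[row]
        if not line[col]:
            # stalk may wiggle: look for a nearby run within the threshold
            near = np.flatnonzero(line)
            if near.size == 0:
                continue
            candidates = near[np.abs(near - col) < width_threshold]
            if candidates.size == 0:
                continue
            col = int(candidates[np.argmin(np.abs(candidates - col))])
        lo = col
        while lo > 0 and line[lo - 1]:
            lo -= 1
        hi = col
        while hi < line.size - 1 and line[hi + 1]:
            hi += 1
        run = hi - lo + 1
        if run >= width_threshold:
            break
        line[lo:hi + 1] = False
        col = (lo + hi) // 2
    if not mask.any():
        raise SegmentationError("no blade found: every row is below the width threshold")
    return mask


def finalize_leaf(mask: np.ndarray, hole_area_threshold: float = 50.0,
                  origin: tuple[int, int] = (0, 0)) -> LeafShape:
    """Keep the largest component, fill small holes, trace contours.

    Foreground components are 8-connected; holes are 4-connected (the
    standard complementary convention).  Holes smaller than
    ``hole_area_threshold`` px² are treated as segmentation noise and
    filled; the remaining holes become the leaf's inner cavities.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask")
    comp = measure.label(mask, connectivity=2)
    areas = np.bincount(comp.ravel())[1:]
    blade = comp == (int(np.argmax(areas)) + 1)

    filled = ndimage.binary_fill_holes(blade)
    holes = filled & ~blade
    hole_labels = measure.label(holes, connectivity=1)
    final = blade.copy()
    cavities = []
    for lbl in range(1, hole_labels.max() + 1):
        hole = hole_labels == lbl
        if hole.sum() < hole_area_threshold:
            final |= hole
        else:
            contour = _longest_contour(hole)
            cavities.append(contour)

    outer = _longest_contour(ndimage.binary_fill_holes(final))
    return LeafShape(final, outer, cavities, tuple(origin))


def _longest_contour(binary: np.ndarray) -> np.ndarray:
    padded = np.pad(binary.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise SegmentationError("no contour found")
    longest = max(contours, key=len)
    return longest - 1.0  # undo padding offset
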