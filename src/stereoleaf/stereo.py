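"""Calibrated binocular stereo: rectification, dense disparity, triangulation.

The rig follows the parallel-axis pinhole model: two identical cameras with
focal length ``f`` (pixels) separated by a horizontal baseline ``B``
(meters).  After rectification a scene point at depth ``Z`` appears in both
images on the same row with a horizontal offset (disparity)

    d = f * B / Z          so that          Z = f * B / d.

Dense matching is normalized-cross-correlation block matching with a
left-right consistency check; the matcher is deliberately interchangeable —
any dense matcher producing a left-referenced disparity map with validity
flags satisfies the downstream contract.  Holes inside a leaf (mismatched or
occluded pixels) are repaired by per-leaf interpolation from valid pixels of
the same leaf only, so depth never bleeds across leaf boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata
from skimage import transform


def spatial_resolution(field_length_mm: float, n_pixels: int) -> float:
    """Ground sampling distance, mm per pixel, of one image axis.

    E.g. a 449.9 mm vertical field imaged over 2056 rows gives 0.2188 mm/px.
    """
    if field_length_mm <= 0 or n_pixels <= 0:
        raise ValueError("field length and pixel count must be positive")
    return field_length_mm / n_pixels


class Validity(IntEnum):
    BACKGROUND = 0
    VALID = 1
    MISMATCH = 2
    OCCLUDED = 3


@dataclass
class CameraRig:
    """Parallel-axis stereo rig: shared intrinsics plus baseline.

    ``rectifying_transform`` holds one 3x3 planar homography per camera
    (row-major, acting on (x, y, 1) pixel coordinates); identity when the
    input imagery is already rectified.
    """

    focal_px: float
    baseline_m: float
    principal_point: tuple[float, float]  # (cx, cy) pixels
    image_size: tuple[int, int]           # (width, height)
    rectifying_transform: tuple = field(default=None)

    def __post_init__(self) -> None:
        if self.focal_px <= 0:
            raise ValueError("focal_px must be positive")
        if self.baseline_m <= 0:
            raise ValueError("baseline_m must be positive")
        if self.rectifying_transform is None:
            self.rectifying_transform = (np.eye(3), np.eye(3))
        self.rectifying_transform = tuple(
            np.asarray(h, dtype=float) for h in self.rectifying_transform)

    @classmethod
    def from_json(cls, path) -> "CameraRig":
        data = json.loads(Path(path).read_text())
        return cls(
            focal_px=data["focal_px"],
            baseline_m=data["baseline_m"],
            principal_point=tuple(data["principal_point"]),
            image_size=tuple(data["image_size"]),
            rectifying_transform=tuple(
                np.asarray(h) for h in data.get(
                    "rectifying_transform", [np.eye(3), np.eye(3)])),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "focal_px": self.focal_px,
            "baseline_m": self.baseline_m,
            "principal_point": list(self.principal_point),
            "image_size": list(self.image_size),
            "rectifying_transform": [h.tolist() for h in self.rectifying_transform],
        }, indent=2))


@dataclass
class StereoFrame:
    left_image: np.ndarray
    right_image: np.ndarray
    rig: CameraRig
    rectified: bool = False

    def __post_init__(self) -> None:
        w, h = self.rig.image_size
        for img in (self.left_image, self.right_image):
            if img.shape[0] != h or img.shape[1] != w:
                raise ValueError("image dimensions do not match rig.image_size")


@dataclass
class DisparityMap:
    """Left-referenced horizontal disparity with per-pixel validity flags."""

    values: np.ndarray
    validity: np.ndarray

    def valid_mask(self) -> np.ndarray:
        return self.validity == Validity.VALID


@dataclass
class LeafPointCloud:
    points: np.ndarray        # (n, 3) X, Y, Z meters
    leaf_label: np.ndarray    # (n,) int
    source_pixel: np.ndarray  # (n, 2) row, col

    def __len__(self) -> int:
        return len(self.points)


def rectify_pair(frame: StereoFrame, rig: CameraRig | None = None) -> StereoFrame:
    """Resample both images by the rig's rectifying homographies.

    After rectification corresponding scene points share a row index
    (horizontal epipolar lines).  Refuses frames already marked rectified.
    """
    if frame.rectified:
        raise ValueError("frame is already rectified")
    rig = rig or frame.rig
    outs = []
    for img, H in zip((frame.left_image, frame.right_image), rig.rectifying_transform):
        H = np.asarray(H, dtype=float)
        if abs(np.linalg.det(H)) < 1e-12:
            raise ValueError("rectifying transform is not invertible")
        if np.allclose(H, np.eye(3)):
            outs.append(img.copy())
            continue
        tform = transform.ProjectiveTransform(matrix=H)
        warped = transform.warp(img.astype(float), tform.inverse, order=1,
                                cval=0.0, preserve_range=True)
        outs.append(warped.astype(img.dtype))
    return StereoFrame(outs[0], outs[1], rig, rectified=True)


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    return img


def _ncc_disparity(left: np.ndarray, right: np.ndarray, d_range: tuple[int, int],
                   window: int, min_corr: float, min_std: float):
    """Winner-take-all NCC cost volume with parabolic sub-pixel refinement.

    Returns (disparity float map, best correlation map).  Disparity is the
    offset of the matching right-image column: x_right = x_left - d.
    """
    h, w = left.shape
    d_min, d_max = d_range
    n_d = d_max - d_min + 1
    size = (window, window)

    mu_l = ndimage.uniform_filter(left, size)
    mu_ll = ndimage.uniform_filter(left * left, size)
    sd_l = np.sqrt(np.maximum(mu_ll - mu_l ** 2, 0.0))
    mu_r = ndimage.uniform_filter(right, size)
    mu_rr = ndimage.uniform_filter(right * right, size)
    sd_r = np.sqrt(np.maximum(mu_rr - mu_r ** 2, 0.0))

    corr = np.full((n_d, h, w), -np.inf)
    for k, d in enumerate(range(d_min, d_max + 1)):
        if d >= w:
            continue
        # right image shifted right by d aligns column x-d under column x
        r_shift = np.full_like(right, np.nan)
        mu_rs = np.full_like(right, np.nan)
        sd_rs = np.full_like(right, np.nan)
        if d >= 0:
            r_shift[:, d:] = right[:, : w - d]
            mu_rs[:, d:] = mu_r[:, : w - d]
            sd_rs[:, d:] = sd_r[:, : w - d]
        mu_lr = ndimage.uniform_filter(left * np.nan_to_num(r_shift), size)
        cov = mu_lr - mu_l * np.nan_to_num(mu_rs)
        denom = sd_l * np.nan_to_num(sd_rs)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where((denom > min_std ** 2) & np.isfinite(mu_rs), cov / denom, -np.inf)
        c[:, :d] = -np.inf
        corr[k] = c

    best_k = np.argmax(corr, axis=0)
    best_c = np.take_along_axis(corr, best_k[None], axis=0)[0]
    disp = best_k.astype(float) + d_min

    # parabolic refinement where both neighbors exist
    km = np.clip(best_k - 1, 0, n_d - 1)
    kp = np.clip(best_k + 1, 0, n_d - 1)
    cm = np.take_along_axis(corr, km[None], axis=0)[0]
    cp = np.take_along_axis(corr, kp[None], axis=0)[0]
    interior = (best_k > 0) & (best_k < n_d - 1) & np.isfinite(cm) & np.isfinite(cp)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = cm - 2.0 * best_c + cp
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (cm - cp) / denom, 0.0)
    disp = np.where(interior, disp + np.clip(delta, -0.5, 0.5), disp)
    return disp, best_c


def compute_disparity(frame: StereoFrame, foreground: np.ndarray,
                      d_range: tuple[int, int] = (0, 64), window: int = 11,
                      min_corr: float = 0.5, min_std: float = 1.0,
                      lr_tol: float = 1.0) -> DisparityMap:
    """Dense left-referenced disparity over the foreground mask.

    NCC block matching (default 11x11 window) scanned over ``d_range``
    followed by a left-right consistency check: pixels whose left and right
    winner disparities disagree by more than ``lr_tol`` px, or whose best
    correlation falls below ``min_corr`` (e.g. textureless regions), are
    flagged MISMATCH; pixels whose right-image match lands outside the frame
    are OCCLUDED; everything outside ``foreground`` is BACKGROUND.
    """
    if not frame.rectified:
        raise ValueError("frame must be rectified before matching")
    fg = np.asarray(foreground, dtype=bool)
    left = _to_gray(frame.left_image)
    right = _to_gray(frame.right_image)
    if fg.shape != left.shape[:2]:
        raise ValueError("foreground mask size mismatch")

    values = np.zeros(left.shape, dtype=float)
    validity = np.full(left.shape, int(Validity.BACKGROUND), dtype=np.uint8)
    if not fg.any():
        return DisparityMap(values, validity)

    disp_l, corr_l = _ncc_disparity(left, right, d_range, window, min_corr, min_std)
    # right-referenced pass: mirror both images horizontally
    disp_r_m, _ = _ncc_disparity(right[:, ::-1], left[:, ::-1], d_range,
                                 window, min_corr, min_std)
    disp_r = disp_r_m[:, ::-1]

    h, w = left.shape
    cols = np.arange(w)[None, :].repeat(h, axis=0)
    match_col = np.round(cols - disp_l).astype(int)
    in_frame = (match_col >= 0) & (match_col < w)
    rows = np.arange(h)[:, None].repeat(w, axis=1)
    d_back = np.where(in_frame, disp_r[rows, np.clip(match_col, 0, w - 1)], np.nan)
    consistent = np.abs(disp_l - d_back) <= lr_tol

    good_corr = np.isfinite(corr_l) & (corr_l >= min_corr)
    valid = fg & good_corr & in_frame & np.nan_to_num(consistent, nan=False)
    occluded = fg & good_corr & ~in_frame
    mismatch = fg & ~valid & ~occluded

    values[valid] = disp_l[valid]
    validity[valid] = Validity.VALID
    validity[occluded] = Validity.OCCLUDED
    validity[mismatch] = Validity.MISMATCH
    return DisparityMap(values, validity)


def repair_disparity(dmap: DisparityMap, leaf_labels: np.ndarray) -> DisparityMap:
    """Fill invalid foreground pixels per leaf from same-leaf valid pixels.

    Piecewise-linear interpolation over the leaf's valid pixels (nearest
    valid same-leaf pixel outside the convex hull of the data); already
    valid pixels are never altered and no leaf ever borrows disparities from
    another leaf.  A leaf with no valid pixel at all is reported
    unreconstructable and left invalid.
    """
    labels = np.asarray(leaf_labels)
    values = dmap.values.copy()
    validity = dmap.validity.copy()
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        leaf = labels == lbl
        valid = leaf & (validity == Validity.VALID)
        holes = leaf & (validity != Validity.VALID)
        if not holes.any():
            continue
        if not valid.any():
            warnings.warn(f"leaf {lbl} has no valid disparities; unreconstructable")
            continue
        src = np.argwhere(valid)
        dst = np.argwhere(holes)
        vals = values[valid]
        if len(src) >= 4:
            filled = griddata(src, vals, dst, method="linear")
        else:
            filled = np.full(len(dst), np.nan)
        nan = ~np.isfinite(filled)
        if nan.any():
            filled[nan] = griddata(src, vals, dst[nan], method="nearest")
        values[holes] = filled
        validity[holes] = Validity.VALID
    return DisparityMap(values, validity)


def triangulate(dmap: DisparityMap, rig: CameraRig,
                leaf_labels: np.ndarray) -> LeafPointCloud:
    """Back-project valid labeled pixels to metric 3-D camera coordinates.

    Z = f * B / d;  X = (col - cx) * Z / f;  Y = (row - cy) * Z / f.
    Pixels with d = 0 (points at infinity) are skipped and counted.
    """
    labels = np.asarray(leaf_labels)
    use = dmap.valid_mask() & (labels > 0)
    n_zero = int((use & (dmap.values <= 0)).sum())
    if n_zero:
        warnings.warn(f"skipping {n_zero} pixels with non-positive disparity")
    use &= dmap.values > 0
    rows, cols = np.nonzero(use)
    d = dmap.values[rows, cols]
    cx, cy = rig.principal_point
    z = rig.focal_px * rig.baseline_m / d
    x = (cols - cx) * z / rig.focal_px
    y = (rows - cy) * z / rig.focal_px
    return LeafPointCloud(
        points=np.column_stack([x, y, z]),
        leaf_label=labels[rows, cols].astype(int),
        source_pixel=np.column_stack([rows, cols]),
    )
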