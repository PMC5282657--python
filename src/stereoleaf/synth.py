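"""Synthetic fixtures with exact ground truth.

Everything the other modules consume can be generated here with known
geometry: parametric leaf blades (round, semi-mosaic, mosaic margins, with
optional interior cavities and a petiole), overlapped round-leaf scenes with
closed-form boundary intersection points, stereo pairs of analytic surfaces
rendered through an ideal pinhole pair (exact per-pixel depth truth),
sampled labeled point clouds, and 3-class Gaussian trait tables.

Every generator is a pure function of its spec plus seed, so fixtures are
bitwise reproducible.  The generated leaves emulate what the rig actually
sees — green blades on brown soil, smooth or serrated margins with known
indent depths, slender petioles — not photorealistic foliage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage.draw import polygon as draw_polygon, disk as draw_disk

from stereoleaf.classify import CLASS_ORDER, FeatureTable
from stereoleaf.geometry import points_to_line_distance
from stereoleaf.stereo import CameraRig, LeafPointCloud, StereoFrame
from stereoleaf.traits import TRAIT_NAMES

LEAF_GREEN = (40, 160, 60)
SOIL_BROWN = (120, 90, 60)

# Default canvas mirrors the rig's 2452 x 2056 sensor scaled down 4x so the
# full pipeline stays fast in tests.
DEFAULT_CANVAS = (514, 613)


@dataclass
class LeafSpec:
    """Parametric leaf blade: ellipse base, sinusoidal marginal teeth, holes."""

    morphology: str = "round"            # round | semi-mosaic | mosaic
    a: float = 120.0                     # semi-major axis, px
    b: float = 90.0                      # semi-minor axis, px
    angle: float = 0.0                   # base-ellipse rotation, rad
    n_teeth: int = 0
    tooth_depth: float = 0.0             # radial modulation depth, px
    n_holes: int = 0
    hole_radii: tuple = ()
    petiole: tuple = (0, 0)              # (width, length) px; (0, 0) = none
    jitter: float = 0.0                  # boundary noise sigma, px
    seed: int = 0
    canvas: tuple = DEFAULT_CANVAS
    center: tuple | None = None          # (row, col); canvas center if None

    def __post_init__(self) -> None:
        if self.morphology not in ("round", "semi-mosaic", "mosaic"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.tooth_depth >= self.b:
            raise ValueError("tooth_depth must be smaller than the minor axis")
        if self.n_holes and len(self.hole_radii) != self.n_holes:
            raise ValueError("hole_radii length must equal n_holes")


def leaf_spec_for(morphology: str, seed: int = 0, **overrides) -> LeafSpec:
    """Canonical spec per morphology: smooth, shallow-toothed, deep-toothed."""
    base = {
        "round": dict(n_teeth=0, tooth_depth=0.0),
        "semi-mosaic": dict(n_teeth=10, tooth_depth=12.0),
        "mosaic": dict(n_teeth=12, tooth_depth=35.0),
    }[morphology]
    base.update(overrides)
    return LeafSpec(morphology=morphology, seed=seed, **base)


def _boundary_polygon(spec: LeafSpec, n_points: int = 4096) -> np.ndarray:
    """Continuous (row, col) boundary polygon, CCW in polar angle."""
    rng = np.random.default_rng(spec.seed)
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    psi = phi - spec.angle
    r = spec.a * spec.b / np.sqrt((spec.b * np.cos(psi)) ** 2
                                  + (spec.a * np.sin(psi)) ** 2)
    if spec.n_teeth > 0 and spec.tooth_depth > 0:
        r = r - spec.tooth_depth * (1.0 - np.cos(spec.n_teeth * phi)) / 2.0
    if spec.jitter > 0:
        # smooth low-order Fourier jitter, preserves closure
        for harmonic in range(2, 7):
            amp = rng.normal(0.0, spec.jitter / np.sqrt(5))
            phase = rng.uniform(0, 2 * np.pi)
            r = r + amp * np.cos(harmonic * phi + phase)
    center = spec.center or (spec.canvas[0] / 2.0, spec.canvas[1] / 2.0)
    rows = center[0] - r * np.sin(phi)
    cols = center[1] + r * np.cos(phi)
    return np.column_stack([rows, cols])


def _tooth_truth_depths(polygon: np.ndarray, spec: LeafSpec) -> np.ndarray:
    """Per-indent chord depths measured on the continuous boundary.

    The tooth tips lie on the convex base ellipse, so the hull chord runs
    tip-to-tip; the depth of each indent is the largest perpendicular
    distance from the arc between two adjacent tips to that chord.  This is
    smaller than the nominal radial ``tooth_depth`` by the sagitta of the
    ellipse arc the chord subtends.
    """
    if spec.n_teeth == 0 or spec.tooth_depth == 0:
        return np.zeros(0)
    n = len(polygon)
    tip_idx = [round(k * n / spec.n_teeth) % n for k in range(spec.n_teeth)]
    depths = []
    for k in range(spec.n_teeth):
        i, j = tip_idx[k], tip_idx[(k + 1) % spec.n_teeth]
        arc = np.arange(i + 1, j) if j > i else np.concatenate(
            [np.arange(i + 1, n), np.arange(0, j)])
        depths.append(float(points_to_line_distance(
            polygon[arc], polygon[i], polygon[j]).max()))
    return np.asarray(depths)


def make_leaf(spec: LeafSpec, rgb: bool = True):
    """Render a leaf image (or mask) plus its analytic truth record.

    Returns ``(image, truth)`` where ``truth`` is a dict holding the exact
    continuous boundary polygon, per-indent chord depths, hole geometry
    (centers, radii, areas, perimeters) and the petiole rectangle.
    """
    rng = np.random.default_rng(spec.seed + 1)
    boundary = _boundary_polygon(spec)
    mask = np.zeros(spec.canvas, dtype=bool)
    rr, cc = draw_polygon(boundary[:, 0], boundary[:, 1], shape=spec.canvas)
    mask[rr, cc] = True

    center = np.asarray(spec.center or
                        (spec.canvas[0] / 2.0, spec.canvas[1] / 2.0))

    holes = []
    min_half = min(spec.a, spec.b) - spec.tooth_depth
    for radius in spec.hole_radii:
        for _ in range(200):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, max(min_half - radius - 6.0, 1.0))
            hc = center + rad * np.array([-np.sin(ang), np.cos(ang)])
            if all(np.hypot(*(hc - np.asarray(h["center"]))) >
                   radius + h["radius"] + 4 for h in holes):
                holes.append({"center": tuple(hc), "radius": float(radius),
                              "area": float(np.pi * radius ** 2),
                              "perimeter": float(2 * np.pi * radius)})
                hr, hcx = draw_disk(hc, radius, shape=spec.canvas)
                mask[hr, hcx] = False
                break

    petiole_rect = None
    if spec.petiole[0] > 0 and spec.petiole[1] > 0:
        width, length = spec.petiole
        bottom = int(np.ceil(boundary[:, 0].max()))
        c0 = int(round(center[1] - width / 2.0))
        top = bottom - 4  # overlap into the blade so they connect
        mask[max(top, 0): min(bottom + int(length), spec.canvas[0]),
             max(c0, 0): min(c0 + int(width), spec.canvas[1])] = True
        petiole_rect = (top, c0, int(width), int(length))

    truth = {
        "boundary": boundary,
        "center": tuple(center),
        "tooth_depths": _tooth_truth_depths(boundary, spec),
        "holes": holes,
        "petiole": petiole_rect,
        "area_analytic": float(np.pi * spec.a * spec.b) if spec.n_teeth == 0
        else None,
    }
    if not rgb:
        return mask, truth
    image = np.empty((*spec.canvas, 3), dtype=np.uint8)
    image[:] = SOIL_BROWN
    image[mask] = LEAF_GREEN
    return image, truth


# --------------------------------------------------------------------------
# Overlapped round-leaf scenes

def circle_intersections(c1, r1, c2, r2):
    """Intersection points of two circles ((row, col) centers), or []."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    d = float(np.hypot(*(c2 - c1)))
    if d == 0 or d > r1 + r2 or d < abs(r1 - r2):
        return []
    a = (r1 ** 2 - r2 ** 2 + d ** 2) / (2 * d)
    h2 = r1 ** 2 - a ** 2
    if h2 < 0:
        return []
    h = np.sqrt(h2)
    mid = c1 + a * (c2 - c1) / d
    perp = np.array([-(c2 - c1)[1], (c2 - c1)[0]]) / d
    if h == 0:
        return [tuple(mid)]
    return [tuple(mid + h * perp), tuple(mid - h * perp)]


def make_overlap_scene(radii, centers, canvas=(400, 400)):
    """Union mask of overlapping disks plus analytic truth.

    Truth holds each disk's center/radius and the circle-circle intersection
    points of every overlapping pair.  Non-overlapping inputs are emitted
    with a warning flag; a disk fully contained in another is flagged
    degenerate.
    """
    mask = np.zeros(canvas, dtype=bool)
    disks = []
    for r, c in zip(radii, centers):
        rr, cc = draw_disk(c, r, shape=canvas)
        mask[rr, cc] = True
        disks.append({"center": tuple(map(float, c)), "radius": float(r)})
    intersections = []
    overlapping = degenerate = False
    for i in range(len(disks)):
        for j in range(i + 1, len(disks)):
            ci, ri = disks[i]["center"], disks[i]["radius"]
            cj, rj = disks[j]["center"], disks[j]["radius"]
            d = float(np.hypot(ci[0] - cj[0], ci[1] - cj[1]))
            if d <= abs(ri - rj):
                degenerate = True
            pts = circle_intersections(ci, ri, cj, rj)
            if pts:
                overlapping = True
                intersections.append({"pair": (i, j), "points": pts})
    truth = {"disks": disks, "intersections": intersections,
             "overlapping": overlapping, "degenerate": degenerate}
    return mask, truth


# --------------------------------------------------------------------------
# Analytic surfaces, stereo rendering and point clouds

@dataclass
class SurfaceSpec:
    """Analytic canopy-like surface with closed-form area and height.

    Kinds (camera looks along +z, scene below the camera):

    * ``plane``: z = z0 over an axis-aligned square of side ``extent`` (m)
      centered on (x0, y0); area = extent².
    * ``tilted_plane``: z = z0 + gx (x - x0) + gy (y - y0) over the same
      square footprint; area = extent² sqrt(1 + gx² + gy²).
    * ``hemisphere``: camera-facing half of a sphere of radius ``radius``
      centered at (x0, y0, z0); area = 2 pi radius².
    * ``paraboloid``: z = z_apex + curv * rho² for rho <= radius, apex
      toward the camera; area = pi/(6 curv²) ((1 + 4 curv² radius²)^1.5 - 1).
    """

    kind: str = "plane"
    z0: float = 1.0
    x0: float = 0.0
    y0: float = 0.0
    extent: float = 0.4
    gx: float = 0.0
    gy: float = 0.0
    radius: float = 0.15
    curv: float = 4.0
    texture_seed: int = 0

    @property
    def true_area(self) -> float:
        if self.kind == "plane":
            return self.extent ** 2
        if self.kind == "tilted_plane":
            return self.extent ** 2 * float(np.sqrt(1 + self.gx ** 2 + self.gy ** 2))
        if self.kind == "hemisphere":
            return 2.0 * np.pi * self.radius ** 2
        if self.kind == "paraboloid":
            k, R = self.curv, self.radius
            return np.pi / (6 * k ** 2) * ((1 + 4 * k ** 2 * R ** 2) ** 1.5 - 1)
        raise ValueError(f"unknown surface kind {self.kind!r}")

    @property
    def z_top(self) -> float:
        """Smallest z on the surface (the canopy point nearest the camera)."""
        if self.kind == "plane":
            return self.z0
        if self.kind == "tilted_plane":
            half = self.extent / 2.0
            return self.z0 - abs(self.gx) * half - abs(self.gy) * half
        if self.kind == "hemisphere":
            return self.z0 - self.radius
        if self.kind == "paraboloid":
            return self.z0
        raise ValueError(self.kind)


class _Texture:
    """Smooth band-limited procedural texture: a seeded sum of sinusoids."""

    def __init__(self, seed: int, wavelength_m: tuple[float, float], n_waves: int = 24):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(*wavelength_m, size=n_waves)
        theta = rng.uniform(0, 2 * np.pi, size=n_waves)
        self.fx = np.cos(theta) / lam
        self.fy = np.sin(theta) / lam
        self.phase = rng.uniform(0, 2 * np.pi, size=n_waves)
        self.amp = rng.uniform(0.4, 1.0, size=n_waves)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(x, dtype=float)
        for fx, fy, ph, am in zip(self.fx, self.fy, self.phase, self.amp):
            acc += am * np.sin(2 * np.pi * (fx * x + fy * y) + ph)
        acc /= np.abs(self.amp).sum()
        return (127.5 + 110.0 * acc).clip(0, 255)


def _surface_depth_along_rays(spec: SurfaceSpec, xn, yn, origin_x: float):
    """Depth z of the first surface hit along rays (xn z + ox, yn z, z)."""
    if spec.kind in ("plane", "tilted_plane"):
        gx = spec.gx if spec.kind == "tilted_plane" else 0.0
        gy = spec.gy if spec.kind == "tilted_plane" else 0.0
        # z = z0 + gx (x - x0) + gy (y - y0) with x = xn z + ox, y = yn z
        denom = 1.0 - gx * xn - gy * yn
        num = spec.z0 + gx * (origin_x - spec.x0) - gy * spec.y0
        z = np.where(np.abs(denom) > 1e-9, num / denom, np.nan)
        x = xn * z + origin_x
        y = yn * z
        inside = (np.abs(x - spec.x0) <= spec.extent / 2) & \
                 (np.abs(y - spec.y0) <= spec.extent / 2) & (z > 0)
        return np.where(inside, z, np.nan)
    if spec.kind == "hemisphere":
        cx, cy, cz, r = spec.x0, spec.y0, spec.z0, spec.radius
        ox = origin_x
        a = xn ** 2 + yn ** 2 + 1.0
        b = 2.0 * (xn * (ox - cx) - yn * cy - cz)
        c = (ox - cx) ** 2 + cy ** 2 + cz ** 2 - r ** 2
        disc = b ** 2 - 4 * a * c
        with np.errstate(invalid="ignore"):
            t = (-b - np.sqrt(disc)) / (2 * a)
        z = t  # ray parameter equals depth since dir z-component is 1
        ok = (disc >= 0) & (z > 0) & (z <= cz)  # camera-facing half only
        return np.where(ok, z, np.nan)
    if spec.kind == "paraboloid":
        k = spec.curv
        ox = origin_x
        # z = z0 + k ((xn z + ox - x0)^2 + (yn z - y0)^2)
        A = k * (xn ** 2 + yn ** 2)
        B = 2 * k * (xn * (ox - spec.x0) - yn * spec.y0) - 1.0
        C = spec.z0 + k * ((ox - spec.x0) ** 2 + spec.y0 ** 2)
        disc = B ** 2 - 4 * A * C
        with np.errstate(invalid="ignore", divide="ignore"):
            z_quad = (-B - np.sqrt(disc)) / (2 * A)
            z_lin = -C / B
        z = np.where(np.abs(A) > 1e-12, z_quad, z_lin)
        x = xn * z + ox
        y = yn * z
        rho2 = (x - spec.x0) ** 2 + (y - spec.y0) ** 2
        ok = np.isfinite(z) & (z > 0) & (rho2 <= spec.radius ** 2)
        return np.where(ok, z, np.nan)
    raise ValueError(f"unknown surface kind {spec.kind!r}")


def render_stereo(spec: SurfaceSpec, rig: CameraRig, background_z: float | None = None):
    """Render the surface into both pinhole cameras with exact depth truth.

    Returns ``(StereoFrame, truth)``; truth carries the left-camera depth
    map, the true disparity map f*B/Z, the surface mask, and the closed-form
    area and canopy height of the surface.  Pixels missing the surface see a
    textured background plane at ``background_z`` (default 1.25x the deepest
    surface point).
    """
    if spec.z_top <= 0:
        raise ValueError("surface must lie entirely in front of the cameras")
    w, h = rig.image_size
    cx, cy = rig.principal_point
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xn = (cols - cx) / rig.focal_px
    yn = (rows - cy) / rig.focal_px

    tex = _Texture(spec.texture_seed, wavelength_m=(
        6 * spec.z0 / rig.focal_px, 50 * spec.z0 / rig.focal_px))
    bg_z = background_z if background_z is not None else 1.25 * (spec.z0 + spec.radius)

    images, depths = [], []
    for origin_x in (0.0, rig.baseline_m):
        z = _surface_depth_along_rays(spec, xn, yn, origin_x)
        zz = np.where(np.isfinite(z), z, bg_z)
        x = xn * zz + origin_x
        y = yn * zz
        img = tex(x, y)
        img[~np.isfinite(z)] *= 0.55  # darken background for visual contrast
        images.append(img.astype(np.uint8))
        depths.append(z)
    depth_left = depths[0]
    mask = np.isfinite(depth_left)
    with np.errstate(divide="ignore", invalid="ignore"):
        true_disp = np.where(mask, rig.focal_px * rig.baseline_m / depth_left, np.nan)
    truth = {
        "depth": depth_left,
        "disparity": true_disp,
        "mask": mask,
        "mask_right": np.isfinite(depths[1]),
        "true_area": spec.true_area,
        "z_top": spec.z_top,
    }
    return StereoFrame(images[0], images[1], rig, rectified=True), truth


def sample_cloud(spec: SurfaceSpec, n: int, noise: float = 0.0,
                 seed: int = 0) -> tuple[LeafPointCloud, dict]:
    """Sample n surface points (uniform over the parameter domain) + truth."""
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    if spec.kind in ("plane", "tilted_plane"):
        x = spec.x0 + spec.extent * (rng.random(n) - 0.5)
        y = spec.y0 + spec.extent * (rng.random(n) - 0.5)
        gx = spec.gx if spec.kind == "tilted_plane" else 0.0
        gy = spec.gy if spec.kind == "tilted_plane" else 0.0
        z = spec.z0 + gx * (x - spec.x0) + gy * (y - spec.y0)
    elif spec.kind == "hemisphere":
        # uniform over the camera-facing half sphere
        u = rng.random(n)
        phi = rng.uniform(0, 2 * np.pi, n)
        cos_t = u  # z-component toward camera in [0, 1]
        sin_t = np.sqrt(1 - cos_t ** 2)
        x = spec.x0 + spec.radius * sin_t * np.cos(phi)
        y = spec.y0 + spec.radius * sin_t * np.sin(phi)
        z = spec.z0 - spec.radius * cos_t
    elif spec.kind == "paraboloid":
        rho = spec.radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        x = spec.x0 + rho * np.cos(phi)
        y = spec.y0 + rho * np.sin(phi)
        z = spec.z0 + spec.curv * rho ** 2
    else:
        raise ValueError(f"unknown surface kind {spec.kind!r}")
    if noise > 0:
        z = z + rng.normal(0.0, noise, n)
    pts = np.column_stack([x, y, z])
    cloud = LeafPointCloud(pts, np.ones(n, dtype=int),
                           np.zeros((n, 2), dtype=int))
    truth = {"true_area": spec.true_area, "z_top": spec.z_top}
    return cloud, truth


def default_rig(width: int = 320, height: int = 240, focal_px: float = 400.0,
                baseline_m: float = 0.08) -> CameraRig:
    """A small test rig: parallel axes, centered principal point."""
    return CameraRig(focal_px=focal_px, baseline_m=baseline_m,
                     principal_point=(width / 2.0, height / 2.0),
                     image_size=(width, height))


# --------------------------------------------------------------------------
# Feature tables

def make_feature_dataset(n_per_class: int = 50, separation: float = 4.0,
                         informative_traits=("FF", "AC"), sigma: float = 1.0,
                         seed: int = 0,
                         class_names=CLASS_ORDER) -> FeatureTable:
    """3-class Gaussian trait table; classes differ only on informative traits.

    Adjacent class means on each informative trait are ``separation`` sigma
    apart; every other trait is i.i.d. N(0, sigma²) noise in all classes.
    """
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for ci, cname in enumerate(class_names):
        block = rng.normal(0.0, sigma, size=(n_per_class, len(TRAIT_NAMES)))
        df = pd.DataFrame(block, columns=TRAIT_NAMES)
        for trait in informative_traits:
            df[trait] += ci * separation * sigma
        frames.append(df)
        labels.extend([cname] * n_per_class)
    features = pd.concat(frames, ignore_index=True)
    return FeatureTable(features, np.asarray(labels))
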