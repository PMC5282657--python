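"""Canopy metrics from a labeled leaf point cloud.

Each leaf's points are triangulated in the horizontal (x, y) projection by a
Delaunay triangulation and lifted to 3-D by reattaching the vertices'
z-coordinates; summing triangle areas over all leaves gives the canopy leaf
area, and plant height is the vertical extent of the cloud above the pot-rim
reference elevation.  A light Laplacian relaxation of the z-coordinates
suppresses matching noise before the area is measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from stereoleaf.stereo import LeafPointCloud


@dataclass
class LeafMesh:
    """Triangulated leaf surface lifted from the xy-plane Delaunay mesh."""

    vertices: np.ndarray   # (n, 3)
    triangles: np.ndarray  # (m, 3) int indices
    leaf_label: int


@dataclass
class CanopyMetrics:
    leaf_area_total: float       # m^2
    per_leaf_area: dict          # label -> m^2
    plant_height: float          # m

    @property
    def leaf_area_total_cm2(self) -> float:
        return self.leaf_area_total * 1e4

    @property
    def plant_height_cm(self) -> float:
        return self.plant_height * 1e2


def remove_isolated_points(cloud: LeafPointCloud, k: int = 8,
                           factor: float = 3.0) -> LeafPointCloud:
    """Statistical outlier removal, applied per leaf.

    A point is dropped when its mean distance to its ``k`` nearest same-leaf
    neighbors exceeds ``factor`` times the leaf's median of those mean
    distances.  Leaves with fewer than k+1 points pass through unchanged.
    """
    keep = np.ones(len(cloud), dtype=bool)
    for lbl in np.unique(cloud.leaf_label):
        idx = np.flatnonzero(cloud.leaf_label == lbl)
        if idx.size < k + 1:
            warnings.warn(f"leaf {lbl} has < {k + 1} points; outlier filter skipped")
            continue
        pts = cloud.points[idx]
        tree = cKDTree(pts)
        dists, _ = tree.query(pts, k=k + 1)
        mean_d = dists[:, 1:].mean(axis=1)
        med = np.median(mean_d)
        if med <= 0:
            continue
        keep[idx[mean_d > factor * med]] = False
    return LeafPointCloud(cloud.points[keep], cloud.leaf_label[keep],
                          cloud.source_pixel[keep])


def delaunay_mesh(cloud: LeafPointCloud,
                  edge_factor: float = 4.0) -> list[LeafMesh]:
    """Per-leaf lifted Delaunay triangulation of the xy-projection.

    Triangles with any projected edge longer than ``edge_factor`` times the
    median projected edge length are dropped, which trims the convex-hull
    bridges the plain Delaunay triangulation spans across concave leaf
    outlines; set ``edge_factor`` to ``inf`` to keep the full triangulation.
    """
    meshes = []
    for lbl in np.unique(cloud.leaf_label):
        pts = cloud.points[cloud.leaf_label == lbl]
        if len(pts) < 3:
            warnings.warn(f"leaf {lbl} has < 3 points; skipped")
            continue
        xy = pts[:, :2]
        if np.linalg.matrix_rank(xy - xy.mean(axis=0), tol=1e-12) < 2:
            warnings.warn(f"leaf {lbl} is collinear in xy; skipped")
            continue
        tri = Delaunay(xy).simplices
        if np.isfinite(edge_factor):
            edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
            lengths = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
            med = np.median(lengths)
            per_tri = lengths.reshape(3, -1).T
            keep = (per_tri <= edge_factor * med).all(axis=1)
            tri = tri[keep]
        if len(tri) == 0:
            warnings.warn(f"leaf {lbl}: no triangles survive edge trimming")
            continue
        meshes.append(LeafMesh(pts.copy(), tri, int(lbl)))
    return meshes


def _vertex_neighbors(n_vertices: int, triangles: np.ndarray):
    neigh = [set() for _ in range(n_vertices)]
    for a, b, c in triangles:
        neigh[a].update((b, c))
        neigh[b].update((a, c))
        neigh[c].update((a, b))
    return [np.fromiter(s, dtype=int) for s in neigh]


def smooth_mesh(mesh: LeafMesh, iterations: int = 5, lam: float = 0.5) -> LeafMesh:
    """Laplacian relaxation of vertex z only; xy and connectivity fixed.

    z <- z + lam * (mean of neighbor z - z), repeated ``iterations`` times.
    A flat mesh is a fixed point.
    """
    verts = mesh.vertices.copy()
    if iterations <= 0:
        return LeafMesh(verts, mesh.triangles.copy(), mesh.leaf_label)
    neigh = _vertex_neighbors(len(verts), mesh.triangles)
    z = verts[:, 2].copy()
    for _ in range(iterations):
        mean_z = np.array([z[nb].mean() if nb.size else z[i]
                           for i, nb in enumerate(neigh)])
        z = z + lam * (mean_z - z)
    verts[:, 2] = z
    return LeafMesh(verts, mesh.triangles.copy(), mesh.leaf_label)


def mesh_area(mesh: LeafMesh) -> float:
    """Surface area as the sum of 3-D triangle areas (cross-product formula)."""
    v = mesh.vertices
    t = mesh.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def canopy_leaf_area(meshes: list[LeafMesh]) -> tuple[dict, float]:
    """Per-leaf and total canopy leaf area in the cloud's length units."""
    per_leaf = {m.leaf_label: mesh_area(m) for m in meshes}
    return per_leaf, float(sum(per_leaf.values()))


def plant_height(cloud: LeafPointCloud, rim_z: float,
                 camera_above: bool = True) -> float:
    """Vertical distance from the pot rim to the highest canopy point.

    With a downward-looking rig, larger z means farther from the camera, so
    the canopy top is the *smallest* z and height = rim_z - min(z).  Set
    ``camera_above=False`` for clouds whose z grows upward.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    z = cloud.points[:, 2]
    height = float(rim_z - z.min()) if camera_above else float(z.max() - rim_z)
    if height <= 0:
        warnings.warn("all points at or below the pot rim; non-positive height")
    return height


def canopy_metrics(cloud: LeafPointCloud, rim_z: float, *,
                   k: int = 8, outlier_factor: float = 3.0,
                   smooth_iterations: int = 5, lam: float = 0.5,
                   edge_factor: float = 4.0,
                   camera_above: bool = True) -> CanopyMetrics:
    """Full chain: outlier removal -> mesh -> smooth -> area + height."""
    cleaned = remove_isolated_points(cloud, k=k, factor=outlier_factor)
    meshes = [smooth_mesh(m, smooth_iterations, lam)
              for m in delaunay_mesh(cleaned, edge_factor=edge_factor)]
    per_leaf, total = canopy_leaf_area(meshes)
    height = plant_height(cleaned, rim_z, camera_above=camera_above)
    return CanopyMetrics(total, per_leaf, height)
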