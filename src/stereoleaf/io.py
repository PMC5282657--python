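"""File glue: ASCII PLY point clouds / meshes, trait CSV, metrics JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stereoleaf.canopy import LeafMesh
from stereoleaf.stereo import LeafPointCloud
from stereoleaf.traits import TRAIT_NAMES, TraitVector

TRAIT_CSV_HEADER = (
    "# stereoleaf trait table: 11 scale-invariant, 3 cavity, 5 margin traits\n"
    "# units: PAR 1/px; APIC, ADI, ADEI px; AAIC px^2; NIC, TNI, ENI counts;"
    " others dimensionless\n"
)


def write_point_cloud_ply(path, cloud: LeafPointCloud) -> None:
    """ASCII PLY with per-vertex x, y, z (meters) and integer leaf_label."""
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(cloud)}",
        "property float x", "property float y", "property float z",
        "property int leaf_label",
        "end_header",
    ]
    body = [f"{x:.6f} {y:.6f} {z:.6f} {lbl}" for (x, y, z), lbl
            in zip(cloud.points, cloud.leaf_label)]
    Path(path).write_text("\n".join(lines + body) + "\n")


def read_point_cloud_ply(path) -> LeafPointCloud:
    text = Path(path).read_text().splitlines()
    n = 0
    for i, line in enumerate(text):
        if line.startswith("element vertex"):
            n = int(line.split()[-1])
        if line == "end_header":
            start = i + 1
            break
    else:
        raise ValueError("not an ASCII PLY file")
    rows = [line.split() for line in text[start:start + n]]
    pts = np.array([[float(v) for v in r[:3]] for r in rows])
    labels = np.array([int(r[3]) if len(r) > 3 else 1 for r in rows])
    return LeafPointCloud(pts, labels, np.zeros((n, 2), dtype=int))


def write_mesh_ply(path, meshes: list[LeafMesh]) -> None:
    """ASCII PLY with all leaf meshes concatenated; faces carry leaf_label."""
    verts, faces, face_labels = [], [], []
    offset = 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.triangles + offset)
        face_labels.extend([m.leaf_label] * len(m.triangles))
        offset += len(m.vertices)
    v = np.vstack(verts) if verts else np.zeros((0, 3))
    f = np.vstack(faces) if faces else np.zeros((0, 3), dtype=int)
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(v)}",
        "property float x", "property float y", "property float z",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
        "property int leaf_label",
        "end_header",
    ]
    body = [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in v]
    body += [f"3 {a} {b} {c} {lbl}" for (a, b, c), lbl in zip(f, face_labels)]
    Path(path).write_text("\n".join(lines + body) + "\n")


def write_trait_csv(path, rows: list[tuple[str, TraitVector]],
                    labels: list[str] | None = None) -> None:
    """Trait table CSV: id column, 19 trait columns, optional label column."""
    records = []
    for k, (sample_id, tv) in enumerate(rows):
        rec = {"id": sample_id, **tv.as_dict()}
        if labels is not None:
            rec["label"] = labels[k]
        records.append(rec)
    df = pd.DataFrame.from_records(records,
                                   columns=["id", *TRAIT_NAMES]
                                   + (["label"] if labels is not None else []))
    with open(path, "w") as fh:
        fh.write(TRAIT_CSV_HEADER)
        df.to_csv(fh, index=False)


def write_metrics_json(path, metrics) -> None:
    Path(path).write_text(json.dumps({
        "leaf_area_cm2": metrics.leaf_area_total_cm2,
        "per_leaf_cm2": {str(k): v * 1e4 for k, v in metrics.per_leaf_area.items()},
        "plant_height_cm": metrics.plant_height_cm,
    }, indent=2))
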