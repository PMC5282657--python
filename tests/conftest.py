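import numpy as np
import pytest

from stereoleaf import segment, synth


@pytest.fixture(scope="session")
def disk_leaf():
    """Rasterized disk of radius 100 px as a LeafShape (closed-form traits)."""
    spec = synth.LeafSpec(a=100, b=100, canvas=(300, 300))
    mask, truth = synth.make_leaf(spec, rgb=False)
    return segment.finalize_leaf(mask), truth


@pytest.fixture(scope="session")
def mosaic_leaf():
    """Deeply serrated leaf (12 teeth, depth 35 px) with analytic truth."""
    spec = synth.leaf_spec_for("mosaic", seed=7, a=180, b=150, canvas=(460, 460))
    mask, truth = synth.make_leaf(spec, rgb=False)
    return segment.finalize_leaf(mask), truth


@pytest.fixture(scope="session")
def holey_leaf():
    """Round leaf with two punched circular cavities of known geometry."""
    spec = synth.LeafSpec(a=120, b=100, n_holes=2, hole_radii=(12.0, 18.0),
                          seed=3, canvas=(340, 340))
    mask, truth = synth.make_leaf(spec, rgb=False)
    return segment.finalize_leaf(mask), truth


@pytest.fixture(scope="session")
def test_rig():
    return synth.default_rig()


def brute_force_indent_depths(contour, hull):
    """Independent margin oracle: pure-python exhaustive point-to-chord scan.

    For each maximal off-hull stretch of contour points, scan every arc
    point and record the largest perpendicular distance to the chord joining
    the bounding hull-contact points.
    """
    pts = np.asarray(contour, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    n = len(pts)
    hull = np.asarray(hull, dtype=float)

    def dist_to_hull(p):
        best = np.inf
        for i in range(len(hull)):
            a, b = hull[i], hull[(i + 1) % len(hull)]
            ab = b - a
            denom = ab @ ab
            t = 0.0 if denom == 0 else max(0.0, min(1.0, (p - a) @ ab / denom))
            proj = a + t * ab
            best = min(best, float(np.hypot(*(p - proj))))
        return best

    contact = np.array([dist_to_hull(p) < 1.0 for p in pts])
    if not contact.any() or contact.all():
        return []
    # walk the contour circularly starting from a contact point; every
    # maximal stretch of non-contact points is an indent candidate bounded
    # by the contact points on either side
    start = int(np.argmax(contact))
    order = [(i + start) % n for i in range(n)]
    depths = []
    i = 0
    while i < n:
        if not contact[order[i]]:
            j = i
            while j + 1 < n and not contact[order[j + 1]]:
                j += 1
            before = pts[order[i - 1]]  # i >= 1 because order[0] is contact
            after = pts[order[(j + 1) % n]]
            ab = after - before
            norm = float(np.hypot(*ab))
            best = 0.0
            for m in range(i, j + 1):
                p = pts[order[m]]
                if norm > 0:
                    d = abs((p[0] - before[0]) * ab[1]
                            - (p[1] - before[1]) * ab[0]) / norm
                else:
                    d = float(np.hypot(*(p - before)))
                best = max(best, d)
            if best >= 4.0:
                depths.append(best)
            i = j + 1
        else:
            i += 1
    return depths
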