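"""Separate two overlapping round leaves from their union silhouette.

Builds the union of two disks, finds the concave points of the simplified
outline (they sit at the circle-circle intersections), cuts the contour
there and fits one ellipse per arc, then compares the recovered radii and
centers with the generating disks.
"""

import numpy as np

from stereoleaf import overlap, synth

mask, truth = synth.make_overlap_scene([80, 60], [(200, 160), (200, 270)],
                                       canvas=(400, 440))
leaves = overlap.split_overlapped_leaves(mask)

print("true disks:")
for d in truth["disks"]:
    print(f"  center ({d['center'][0]:.0f}, {d['center'][1]:.0f}), "
          f"radius {d['radius']:.0f} px")
print("analytic boundary intersections:",
      [tuple(round(float(v), 1) for v in p)
       for p in truth["intersections"][0]["points"]])
print()
print("recovered leaves:")
for leaf in leaves:
    (r, c), a, b, _ = leaf.ellipse
    print(f"  center ({r:.1f}, {c:.1f}), mean radius {(a + b) / 2:.2f} px, "
          f"axis ratio {a / b:.3f}")
print()
print("Each recovered ellipse should match one generating disk to within a")
print("few percent in radius and a few pixels in center; the method only")
print("applies to round-leaf morphology, whose blades are near-elliptical.")
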