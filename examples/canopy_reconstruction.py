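"""Stereo canopy reconstruction on a rendered analytic surface.

Renders a textured paraboloid "canopy" (apex toward the camera, bounded
slope like a real seedling rosette) into a calibrated stereo pair, runs
dense NCC matching, repairs and triangulates the disparity, meshes the
cloud, and compares measured leaf area and plant height with the closed
forms.  Note that a surface with near-vertical flanks (e.g. a full
hemisphere) would under-report area: top-view stereo cannot sample
edge-on surface patches.
"""

import numpy as np

from stereoleaf import canopy, stereo, synth

rig = synth.default_rig(width=320, height=240, focal_px=400.0, baseline_m=0.08)
spec = synth.SurfaceSpec(kind="paraboloid", z0=0.85, radius=0.18, curv=2.0,
                         texture_seed=5)
frame, truth = synth.render_stereo(spec, rig)

dmap = stereo.compute_disparity(frame, truth["mask"], d_range=(0, 48))
labels = truth["mask"].astype(int)
dmap = stereo.repair_disparity(dmap, labels)
cloud = stereo.triangulate(dmap, rig, labels)

rim_z = 1.10  # pot rim 25 cm below the canopy apex
metrics = canopy.canopy_metrics(cloud, rim_z=rim_z)

true_area_cm2 = truth["true_area"] * 1e4
true_height_cm = (rim_z - truth["z_top"]) * 1e2
print(f"triangulated points : {len(cloud)}")
print(f"leaf area           : {metrics.leaf_area_total_cm2:8.1f} cm^2 "
      f"(truth {true_area_cm2:.1f})")
print(f"plant height        : {metrics.plant_height_cm:8.1f} cm "
      f"(truth {true_height_cm:.1f})")
print()
print("Leaf area sums the 3-D triangle areas of the per-leaf lifted Delaunay")
print("mesh; plant height is the vertical distance from the pot rim to the")
print("canopy point nearest the camera.")
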