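# Methods

This note records the models, parameter choices and numerical decisions
behind `stereoleaf`, and what the synthetic fixtures do and do not show
about real imagery.

## Stereo model and matching

The rig is two identical pinhole cameras with parallel optical axes,
focal length `f` (pixels), baseline `B` (meters), and a shared principal
point convention; world *z* points from the camera into the scene, so the
canopy top is the *smallest* z. After rectification (application of
per-camera planar homographies, bilinear resampling, black fill) the
disparity of a point at depth *Z* is `d = f·B/Z`, and triangulation is the
exact inverse: `Z = f·B/d`, `X = (col − cx)·Z/f`, `Y = (row − cy)·Z/f`.

Dense matching is zero-mean NCC block matching (default window 11×11,
disparity range configurable, winner-take-all with parabolic sub-pixel
refinement). Any dense matcher meeting this output contract is
interchangeable. Pixels are invalidated when

* the best correlation falls below 0.5 or the window is (near-)textureless
  (standard deviation floor 1.0 gray level) — *mismatch*;
* the left and right winner disparities disagree by more than 1 px —
  *mismatch*;
* the implied match column lies outside the right frame — *occluded*.

Holes inside a labeled leaf are repaired by piecewise-linear interpolation
over that leaf's valid pixels (nearest-valid fallback outside their convex
hull). Linear interpolation is exact on planar patches, which is also the
regime of the repair fixtures; pixels are never borrowed across leaf
labels and valid pixels are never altered. Leaves with no valid pixel are
reported unreconstructable rather than filled.

## Canopy metrics

Per leaf, points are filtered by a k-nearest-neighbor statistical outlier
rule (k = 8, factor 3× the leaf median of mean k-NN distances), Delaunay
triangulated in the xy-projection and lifted to 3-D. Triangles with any
projected edge longer than 4× the median edge are dropped, which trims the
convex-hull bridges a plain Delaunay triangulation spans across concave
outlines. Vertex z-coordinates are relaxed by 5 iterations of
`z ← z + 0.5·(mean neighbor z − z)`; a flat mesh is a fixed point, and on
a fronto-parallel noisy plane every additional iteration reduces the
z-RMSE (the relaxation is exactly shape-preserving there; on tilted
surfaces many iterations flatten the boundary, which is why the default
stays at 5). Leaf area is the sum of 3-D triangle areas; at 5,000 sampled
points a hemisphere's area is recovered within ~3% (the residual sits at
the steep rim, where the xy-projected sampling thins). Plant height needs
the pot-rim elevation `rim_z` as configuration; automatic rim detection is
out of scope. Height is an extreme statistic — a relative depth error ε at
the canopy top produces a height error of ε·Z, so shallow canopies carry
proportionally larger height errors than deep ones.

## Leaf segmentation

Canopy-level foreground is `g/(r+g+b) > 0.40` with a brightness floor of
20/255 (both configurable; the thresholds separate green foliage from
gray/brown soil on the fixtures). Single-leaf foreground uses
`ExG − ExR > 0`. Stems/petioles: at canopy level a disk opening of radius
5 px; at leaf level a bottom-up scan that clears the contiguous foreground
run containing the petiole column while its width is strictly below 25 px,
stopping at the blade shoulder. The run is tracked by its center column so
a tilted stalk is followed; the boundary case (run exactly at threshold)
is retained. The largest 8-connected component is kept, holes (4-connected,
the complementary convention) below 50 px² are filled, and the remainder
become inner cavities.

## Trait numerics

* **Area** is the mask pixel count; **perimeter** is the length of the
  sub-pixel marching-squares contour after a 5-point circular moving
  average. The raw contour staircases at the pixel scale and overstates
  smooth perimeters by ~5%; the averaged polygon is within +0.3% on a
  disk and −1% on a square, and the same measure is used for PC, FF, PAR
  and cavity perimeters so ratios stay consistent.
* **Bounding primitives**: rotated minimum-area rectangle, convex hull
  (polygon length/area), maximum of the interior distance transform
  (inscribed circle), minimum enclosing circle, and a direct least-squares
  conic ellipse fit with a second-moment fallback.
* **Fractal dimensions** are box-counting slopes over dyadic grids of
  8–128 boxes across the square-padded frame. Grid sizes scale with the
  frame, making the estimate invariant under joint rescaling of shape and
  canvas; the coarse 4-box grid is excluded because it dominates slope
  noise. SFD uses the full crop canvas ("without cropping"), IFD the tight
  bounding-box crop.
* **Margin traits**: contour points within 1 px of the hull are serration
  points; every maximal off-hull arc is an indent whose depth is the
  largest perpendicular distance to the chord joining its bounding
  serration points (that chord lies along a hull edge). Indents shallower
  than 4 px are discarded as raster noise — the floor must exceed the
  contact tolerance plus the pixel quantization margin, otherwise a flat
  tooth tip that momentarily dips off the hull masquerades as a shallow
  indent. Effectiveness divides depth by half the smaller rotated-box
  side; the 0.3 threshold is strict (`>`). AVE averages effectiveness over
  *all* counted indents, which is the reading of "average calculated value
  of effectiveness" adopted here.

## Overlapped round leaves

The union outline is Douglas–Peucker simplified (tolerance 3 px; the ring
is rolled to start at the point farthest from the centroid so the
always-kept start vertex lies on the true outline). Concave vertices
(cross-product sign against polygon orientation, winding-independent) cut
the full-resolution contour; arcs shorter than 10% of the contour merge
into their neighbor; each arc gets a direct least-squares ellipse fit, and
fits whose implied ellipse dwarfs the arc's extent (10×) are rejected as
degenerate. Ellipses overlapping a larger-support ellipse by more than
80% (intersection over smaller area) are collapsed. The method presumes
near-elliptical blades and is exposed but documented as round-leaf-only.

## Classification

Wilks' Λ = det(W)/det(T) on the candidate trait set; entry F for adding a
(p+1)-th variable is `((n−g−p)/(g−1))·(Λ_p/Λ_{p+1} − 1)`. Defaults
F-to-enter 3.84 / F-to-remove 2.71 (the conventional stepwise pair). With
17 pure-noise candidates, the best-of-17 entry test admits a noise trait
in roughly a third of runs and occasionally two — the informative traits
still always enter first. Canonical functions come from the generalized
eigenproblem `B v = λ W v` (tiny ridge on W for numerically singular
scatter); samples map into the 2-D canonical space and take the nearest
class centroid, ties to the lowest class index. When no variable
qualifies, evaluation falls back to a fixed prior-free class (the first in
sort order); the modal class would be systematically *anti*-correlated
under leave-one-out, where the held-out class is always one sample short.

SVM: features min-max scaled to [0,1] on training statistics only (test
values may fall outside), polynomial kernel `(γ⟨x,y⟩)³` with γ = 1.5 and
penalty C = 2, one-vs-one multiclass. Degree 3 is a documented choice;
γ and C are configurable. Random forest: majority vote, default 1000
trees, explicit seed (default 20170131). Leave-one-out evaluation refits
scaling and stepwise selection inside every fold.

## Synthetic fixtures: what they show and what they don't

The generator produces green-on-brown rasters of parametric blades
(ellipse base, sinusoidal radial teeth, circular holes, rectangular
petiole, low-order Fourier boundary jitter), overlapped-disk scenes with
closed-form intersection points, stereo renders of analytic surfaces by
exact per-pixel ray/surface intersection with a band-limited sinusoid-sum
texture, uniformly sampled labeled clouds, and 3-class Gaussian trait
tables. The default canvas mirrors the rig's 2452×2056 sensor scaled down
4×, which keeps full-pipeline runs fast. Truth records are computed from
the continuous geometry (e.g. per-tooth chord depths by exhaustive
point-to-chord scan on the pre-raster polygon), so downstream checks never
re-derive geometry from the raster under test.

Per-tooth chord depth is *not* the nominal radial modulation depth: the
hull chord subtends an ellipse arc whose sagitta reduces the perpendicular
depth, which is why truth depths are measured, not assumed.

These fixtures exercise geometry, not photometry: there is no specular
leaf gloss, no shadowing, no chlorosis or soil clutter, no calibration
error, and texture is guaranteed matchable. Passing tests therefore
establish correctness of the geometric and statistical machinery, not
field robustness of the color thresholds or the matcher on real crops.

Problem sizes used by the test suite and acceptance script (disks of
radius 100–300 px, 5,000-point surface samples, 200 overlap scenes,
150-sample trait tables, 20 stepwise seeds) were chosen to keep the full
run in the low minutes while leaving each check's tolerance comfortably
above its measurement noise.

## Known limitations

* The disparity-repair and mesh-smoothing procedures are principled
  reconstructions of briefly described steps, not re-implementations of a
  published algorithm; area metrics are insensitive to the smoothing
  choice on smooth fixtures, but equivalence to any particular prior
  implementation cannot be claimed.
* The fractal-dimension estimator is one defensible box-counting variant;
  absolute SFD/IFD values are estimator-specific and should only be
  compared within this package.
* Eq.-style effectiveness uses the rotated minimum-box sides; an
  axis-aligned reading would differ on elongated tilted leaves.
* Overlap recovery assumes exactly round blades; serrated morphologies
  produce concave points everywhere and are explicitly unsupported.
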