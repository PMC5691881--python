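# Methods

## Measurement model

A vertebral body is represented as a watertight triangle mesh with per-vertex
region labels (upper endplate, lower endplate, lateral wall) and two midline
landmarks: `a` and `b`, the anterior edges of the vertebral foramen on the
upper and lower endplates. Posterior elements are assumed already removed;
segmentation is out of scope.

The intrinsic frame is built as follows. The center of gravity `G` is the
centroid of the enclosed solid at uniform density, computed by signed-
tetrahedron decomposition (exact for watertight, consistently oriented
meshes). The vertical axis is the unit vector from `b` to `a` (caudal to
cranial), translated to pass through `G`. The sagittal plane contains `G`,
`a` and `b`; the anterior direction is the component of `G − midpoint(a, b)`
orthogonal to the vertical axis, and left/right is the sign against
`vertical_axis × anterior_dir`. The construction is equivariant under rigid
motions and invariant under uniform scaling, and the tests assert both.

Measurement points: the sagittal plane is rotated about the vertical axis by
+45°, −45° and +90°. Each rotated plane must cross the lower-endplate rim
exactly twice (anything else is reported as an error naming the plane angle).
The +90° (coronal) crossings are the middle pair; each ±45° plane contributes
one anterior and one posterior point by the sign of its anterior-direction
component. Heights are perpendicular point-to-plane distances to the
total-least-squares plane of the upper-endplate vertex set — distances to the
plane, not distances along the vertical axis; the upper endplate always
supplies the fitted plane and the lower endplate always supplies the points,
and the convention is never swapped per vertebra. VHR per part is concave
height ÷ convex height, with the curve's laterality (`concave_side`) taken as
an input: a single vertebra cannot know which side of the whole-spine curve it
sits on. Outputs are rounded to 3 decimals for display only.

Endplate delineation on the original workstation was manual; here region
labels are the contract. An unlabeled fallback exists (faces whose outward
normal lies within 40°, configurable, of ±axis; largest connected component),
but labeled meshes always win.

## Geometry primitives and numerical choices

* Total-least-squares plane fit via SVD of the centered cloud; degenerate
  (collinear) sets are rejected when the second singular value vanishes
  relative to the first. Normal orientation is made deterministic by forcing
  the largest-magnitude component positive.
* Rim/plane intersection adds +1e−12 mm to every signed vertex distance, so a
  vertex lying exactly on a cutting plane yields exactly one crossing — the
  generator's grids otherwise place nodes exactly on the ±45° planes.
* All geometry is in millimetres, right-handed; angles are degrees at the API
  surface and radians internally.
* If concave and convex heights are equal the ratio is exactly 1; no
  tie-break is needed.

## Densitometry

The sphere center is the per-axis midpoint of the body's bounding extents
(its center as seen on the axial, coronal and sagittal planes). The radius is
the distance from the center to the nearest non-trabecular voxel center minus
half the largest voxel spacing — a safety margin guaranteeing the sphere
excludes the cortical margin under any membership rule — floored at one voxel
with a warning. Voxel membership is center-inside-sphere; the mean HU is over
member voxels. "Largest possible sphere" was a visual fit on the clinical
workstation; the distance-based maximality here is this package's
formalization (the tests verify that one extra voxel of radius would touch
cortical or outside voxels). For volumes without an explicit cortical label a
threshold rule (cortical = HU ≥ 400, configurable) is provided.

## Radiographic indices

Cobb angle is the acute angle between two endplate lines (degrees, [0, 90]).
The flexibility index is computed per curve, then summarized —
`FI(erect means)` is not the mean of per-curve FIs, so the pipeline never
computes FI from group means. Structural classification uses the standard
residual-bending threshold of 25° (boundary inclusive, configurable); the
structural curve is the main curve, otherwise the largest erect Cobb wins,
with erect ties broken toward the more caudal apex (a case the data never
produce, handled deterministically).

## Synthetic-data generator

`generate_vertebra_mesh` builds an elliptical-cylinder body: lower endplate in
a base plane (lateral semi-axis `r_x`, AP semi-axis `r_y`), upper endplate a
plane wedged by a coronal tilt φ about the AP axis (realized as a vertical
shear, so the upper cap is exactly planar and the fitted plane is exact), and
a waisted lateral wall (mid-wall radial scale 0.92). Landmarks sit at the
posterior rim midline — a stand-in for the anterior foramen edges, since no
posterior elements are meshed. The closed form for this geometry is

```
height(x) = (H ± x·tanφ)·cosφ      (+ convex side, − concave side)
VHR(x)    = (H − x·tanφ) / (H + x·tanφ)
```

with `x = r_x` at the middle and `x = r_x·r_y / √(r_x² + r_y²)` at the
±45°-plane crossings of the ellipse. `analytic_vhr` is the independent oracle;
the central test suite asserts pipeline/oracle agreement within 0.005 across a
tilt × size grid (residual discrepancy ~2 × 10⁻³ at worst comes from the rim
polygon discretization and the small lateral shift of the centroid in wedged
bodies).

Cohorts: defaults are the study conditions — 12 NS patients × 1 curve and 13
IS patients × 2 curves, 3 vertebrae (apical ± 1) per curve, i.e. 36 and 78
vertebral models. Per vertebra a true VHR triplet is drawn per part from the
group's normal distribution (means/SDs are the reported group values),
truncated to (0.5, 1.1]; normality is an assumption — only means and SDs are
reported — and the truncation keeps the geometry valid. A single tilt φ is
then solved so the *middle* drawn ratio is realized exactly at the drawn body
size (`r_x` uniform on 16–20 mm, height on 19–24 mm); a single rigid endplate
tilt cannot realize three independent ratios, so the anterior/posterior
realized values follow geometrically and the residual mismatch against the
independent anterior/posterior draws is recorded in the truth output. With
the default body aspect `r_y = 0.75·r_x` (vertebral bodies are wider than
deep) the 45°-plane offset is 0.6·r_x, which makes the realized IS-main
anterior group mean land within ~0.002 of its generating mean — the
anatomically natural aspect is also the self-consistent one. Note the
realized posterior ratio is geometrically identical to the anterior one in
this generator. Draws requiring |φ| ≥ 15° (several SDs below the group means)
are clamped at 14.5°.

Cobb pairs are drawn from the group normals with `0 ≤ bending ≤ erect`
enforced by redraw. For the compensatory curve (bending 4.5 ± 10.8°) the
redraw raises the realized bending mean, compressing the flexibility index
toward ~78% rather than the reported 93 ± 37% — values above 100% would
require beyond-midline correction that a non-negative Cobb angle cannot
express. HU is drawn per vertebra from the curve type's normal; curve-level
HU is the mean of its three vertebrae. Each patient consumes an independent
substream of the master seed, so cohorts are reproducible and group sizes can
change without reshuffling others. Within-patient correlation of the three
vertebrae is unknown from the reported data; the generator defaults to
independence with an optional patient-level random effect (off by default).

What the phantoms do **not** emulate: real vertebral anatomy (processes,
pedicles, endplate concavity), axial rotation, imaging noise or partial-volume
effects, and segmentation error. Passing tests therefore validate the
measurement and statistics given correct surfaces and masks, not robustness to
upstream segmentation.

## Statistics

`mann_whitney_u` uses midranks; `U = min(U1, U2)`. The p-value is exact (full
enumeration of rank assignments, both tails) when the combined sample size is
≤ 12 with no ties, otherwise a normal approximation with tie and continuity
corrections. An all-identical pooled sample returns p = 1. Tests check the
exact path against independent enumeration for every untied configuration up
to combined n = 10 and the approximate path against a 10⁵-permutation Monte
Carlo oracle.

The study report compares VHR at vertebra level (each of the three vertebrae
per curve is one observation, n = 36 vs 39), matching the apparent original
analysis; this ignores within-patient clustering, which would understate
p-values if vertebrae within a curve were positively correlated — a
`patient_mean` unit is available. HU, Cobb and FI are compared at curve level
(n = 12/13/13), age at patient level at α = 0.05; all curve variables use the
Bonferroni-adjusted α = 0.05/3 (displayed as 0.017). Display rounding: p to 3
decimals, "<0.001" below that.

Calibration tests run the cohort generator without meshes and analyze the
realized (analytically measured) ratios: the mesh pipeline reproduces those
values within 0.005, negligible against group SDs of 0.04–0.09, and this
keeps 700 replicates inside seconds. Problem sizes used: 500 null replicates
(type-I rate over the anterior and middle comparisons — posterior duplicates
anterior in this generator and is excluded from the trial count) and 200
power replicates at the default distributions.

## Known limitations

* Wedging is purely coronal (a single tilt); sagittal wedging, torsion and
  per-part independent deformation are not modeled.
* The center of gravity is computed on the body-only mesh; whether the
  original measurement used the full vertebra is not documented.
* Heights are perpendicular to the fitted upper plane; an axis-parallel
  convention would differ by a cosφ-scale factor at large tilts.
* Compensatory-curve FI is biased low relative to the reported group value
  (see above); no downstream check depends on it.
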