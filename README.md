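# vertmorph

3D morphometry of vertebral bodies for scoliosis research: coronal wedge
quantification from surface meshes, spherical-ROI CT densitometry, radiographic
curve indices, and nonparametric group statistics — with a synthetic-data
module that makes the whole pipeline verifiable without patient data.

## The scientific problem

In scoliosis, vertebral bodies around the apex of a lateral curve become
wedge-shaped in the coronal plane: the concave side grows shorter than the
convex side. Whether this wedging is purely a secondary response to asymmetric
loading or partly a primary growth disturbance differs between etiologies —
neuromuscular scoliosis (NS, e.g. in Duchenne muscular dystrophy) is driven by
muscle weakness, while idiopathic scoliosis (IS) may involve asymmetric
vertebral growth itself. Comparing the two requires a reproducible, truly 3D
measure of wedging, because vertebral rotation makes plain radiographs
misleading.

The core quantity is the **vertebral height ratio (VHR)**

```
VHR = d / D
```

where `d` is the concave-side and `D` the convex-side height of the vertebral
body, measured at the anterior, middle and posterior of the body. Parallel
endplates give VHR = 1; coronal wedging pushes it below 1.

Per vertebra the measurement is:

1. **Intrinsic frame** — center of gravity `G` of the body mesh; vertical axis
   parallel to the line `a–b` joining the anterior edges of the vertebral
   foramen on the upper and lower endplates; sagittal plane through `G`, `a`,
   `b`.
2. **Measurement points** — the sagittal plane is rotated about the vertical
   axis by ±45° and +90°; each rotated plane crosses the lower-endplate rim
   twice, giving the anterior, middle (coronal) and posterior left/right pairs.
3. **Heights** — perpendicular distances from those six points to the
   total-least-squares plane fitted to the upper endplate.
4. **Ratios** — concave height ÷ convex height per part.

Around the measurement sit: largest-interior-sphere Hounsfield-unit (HU)
densitometry of the trabecular body on CT (a bone-mineral-density surrogate),
Cobb angles and the flexibility index `FI(%) = (erect − bending) / erect × 100`
with structural/main/compensatory curve assignment, and pairwise Mann–Whitney U
comparisons of the NS major, IS main and IS compensatory curve groups at the
Bonferroni-adjusted level 0.05/3 ≈ 0.017.

## Worked example

```python
import numpy as np
from vertmorph import (VertebraSpec, analytic_vhr, generate_vertebra_mesh,
                       measure_vertebra, flexibility_index)

# a wedged body: circular endplates r = 20 mm, height 25 mm, 3 deg coronal tilt
spec = VertebraSpec(r_x=20, r_y=20, height=25, tilt_deg=3.0)
print(measure_vertebra(generate_vertebra_mesh(spec)).triplet)
print(analytic_vhr(spec))
print(round(flexibility_index(73.0, 31.8), 1))
```

prints

```
[0.9425033  0.91956927 0.94241668]
[0.94241456 0.9195217  0.94241456]
56.4
```

The mesh pipeline reproduces the closed-form ratios of the generated geometry
to better than 5 × 10⁻³ (here ~1 × 10⁻⁴): the middle ratio is
`(H − r·tanφ)/(H + r·tanφ)` and the anterior/posterior ratios use the 45°-plane
rim offset `r/√2`. The last line is the flexibility index of a curve measuring
73.0° erect and 31.8° on bending films.

A full synthetic study — 12 NS patients (36 vertebral models) and 13 IS
patients (78 models), measured end to end and compared group-wise — runs from
the shell:

```bash
vertmorph reproduce --seed 7 --out out/
# out/measurements.csv  per-vertebra measured VHR and HU
# out/vhr_by_curve.csv  per-curve VHR mean ± SD (anterior/middle/posterior)
# out/report.json       all pairwise Mann-Whitney comparisons
```

Other subcommands: `simulate` (write PLY meshes + landmark JSONs + truth CSV),
`measure` (VHR from mesh + landmark files), `hu` (spherical-ROI densitometry on
NIfTI/NRRD volumes), `indices` (FI and curve roles from a Cobb CSV), `stats`
(group comparisons from measurement CSVs).

In Python, the study layer follows the model/results idiom:

```python
from vertmorph import CohortSpec, ScoliosisStudy, generate_cohort

cohort = generate_cohort(CohortSpec(), seed=7)
results = ScoliosisStudy(cohort.measure(), **{
    k: v for k, v in cohort.to_frames().items() if k != "vertebrae"
}).fit()
print(results.summary())
```

## Documentation

`docs/methods.md` describes the measurement model, the synthetic-data
generator and its calibration, numerical choices and known limitations.
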