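# esovol

Semiautomatic CT volumetry of esophageal tumors, with the observer-agreement
statistics used to validate it.

Esophageal tumor volume on staging CT is clinically interesting (response
assessment, prognosis) but hard to measure reproducibly: the tumor's contrast
against the normal esophageal wall is low and its cranial and caudal borders
are ambiguous, so two readers tracing the same tumor slice by slice can
disagree substantially. `esovol` implements the workflow that mitigates
this — sparse key-slice delineation with software interpolation and
Hounsfield-unit thresholding — together with the statistical toolbox needed
to quantify whether it actually improves reader agreement. It is aimed at
imaging researchers who want a reproducible, scriptable version of what a
volumetry workstation does, plus a synthetic testbed with known ground truth.

## What it computes

**Volumetry.** A tumor volume is the summation-of-area (Breiman) estimate

V = Σₖ Aₖ · Δz,

with Aₖ the cross-sectional tumor area on axial slice k and Δz the slice
thickness (reported in ml). Areas come either from closed planar contours
(shoelace formula) or from voxel masks (pixel-center rasterization). In the
semiautomatic path the reader draws only the first and last tumor-bearing
slices and slices with clear morphologic change; every intermediate slice is
filled in by linear interpolation of the key slices' signed Euclidean
distance maps (negative inside the contour), and the result is intersected
with an HU window, by default [0, 1000] HU, which removes intraluminal air
while keeping all soft tissue. Manual segmentation rasterizes one drawn
contour per slice, with no HU window. Volumes are read on a 2.5 mm
average-intensity reformat of the native 0.625 mm slices, as at a
workstation.

**Agreement.** For paired measurements (two readers, or two contrast phases
within a reader) the package computes single-measures intraclass correlation
coefficients in the three Shrout–Fleiss forms — one-way random ICC(1,1),
two-way random absolute agreement ICC(2,1), two-way mixed consistency
ICC(3,1) — with F-based 95% CIs; the Fisher r-to-z test
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) for comparing two ICCs;
Bland–Altman limits of agreement (mean difference ± 1.96 × SD of the paired
differences); and the mean absolute percentage difference from the pair
mean, 100·|v₁−v₂|/(v₁+v₂) per item.

**Synthetic testbed.** A phantom generator renders tapered tubular tumors
with known analytic volume in CT-realistic intensities, and an observer
model (smooth radial tracing noise plus Gaussian error in the cranial/caudal
extent) lets the full two-reader, two-method, two-phase experiment run end
to end against ground truth.

**Study reproduction.** The package ships the measurement table of a
published 23-patient, two-reader esophageal volumetry study (integer ml per
patient × method × observer × phase, integrity-gated on the published column
means) plus per-patient histology, and recomputes the study's headline
statistics from them.

## Worked example

`examples/02_agreement_statistics.py` forms the 46 interobserver pairs
(resident vs consultant, both contrast phases entering as separate items)
for each segmentation method from the packaged study table and prints:

```
manual    n=46
  ICC(2,1)            : 0.56  (95% CI -0.09-0.84)
  Bland-Altman        : mean diff -25.5 ml, LoA [-53.8, 2.8] ml, width 56.6 ml
  abs. pct. difference: 31.8 %  (95% CI 26.3-37.3)
semiauto  n=46
  ICC(2,1)            : 0.86  (95% CI 0.57-0.94)
  Bland-Altman        : mean diff -7.9 ml, LoA [-28.1, 12.4] ml, width 40.5 ml
  abs. pct. difference: 14.2 %  (95% CI 9.0-19.3)

Fisher r-to-z, semiauto vs manual ICC: z = 3.14, p = 0.0017
```

Read: with manual slice-by-slice tracing the two readers correlate only
moderately (ICC 0.56) and a reader deviates from the pair mean by 32% on
average; with key-slice interpolation agreement rises to 0.86 and the
deviation halves to 14%, a significant difference (p < 0.01). The other
examples cover segmentation of a phantom (`01`), the full study
recomputation (`03`) and the simulated experiment (`04`).

A thin CLI mirrors the library:

```bash
esovol segment --vol vol.nii.gz --keys keys.json --out mask.nii.gz
esovol volume --mask mask.nii.gz --vol vol.nii.gz
esovol agree --table measurements.csv --method semiauto --analysis interobserver
esovol reproduce --out report.json
```

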