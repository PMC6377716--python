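# Methods

This note documents the models, algorithms and numerical choices behind
`esovol`, in the order of the measurement chain.

## Image model and reformatting

Volumes are held as `(z, y, x)` arrays of Hounsfield units with spacing
`(dx, dy, dz)` in mm. The in-plane origin is the physical position of the
first pixel *center*; along z the origin marks the start of the first slab,
so slice `k` occupies `[z0 + k·dz, z0 + (k+1)·dz)` and its center sits at
`z0 + (k+0.5)·dz`. This slab convention keeps slice membership stable under
reformatting, which merges whole slabs. HU values are clamped to the 12-bit
CT range `[-1024, 3071]` on load so scanner padding values cannot leak
through the threshold logic.

`reformat_axial` implements the average-intensity projection used before
reading: groups of `m = round(target/dz)` thin slices are replaced by their
voxelwise mean. The target must be an integer multiple of `dz` (for the
0.625 mm acquisitions and the 2.5 mm reading thickness, `m = 4` exactly);
trailing slices that do not fill a complete group are dropped rather than
partially averaged, so the output slice count is reproducible. The retained
slab's volume-weighted mean HU is preserved exactly (the operation is a
block mean).

## Contours and rasterization

Delineations are simple closed polygons in physical mm, one per axial
slice, validated on construction (≥ 3 vertices, nonzero shoelace area,
shapely simplicity check). Storing mm rather than pixel indices makes a
contour meaningful on any grid the volume is resampled to. Area is the
shoelace formula; rasterization includes a pixel iff its center lies inside
the polygon, the standard unbiased area estimator (any-overlap rules bias
areas upward by roughly one perimeter-times-half-pixel band). Point-in-
polygon testing uses `matplotlib.path`; note the closing vertex must be
supplied explicitly because `Path(..., closed=True)` treats the last given
vertex as the close-poly placeholder.

The on-disk contour format is a minimal versioned JSON schema
(`esovol-contours v1`) with 0-based slice indices and full-precision
vertices, since the workstations that produce such delineations use
proprietary formats.

## Shape-based interpolation and HU windowing

The semiautomatic core interpolates between consecutive key slices `a < b`:
both key contours are rasterized, each mask is converted to a signed
Euclidean distance map in mm (`scipy.ndimage.distance_transform_edt`,
negative inside), and intermediate slice `k` takes the set
`{(1−t)·D_a + t·D_b < 0}` with `t = (k−a)/(b−a)`. Key slices keep their
rasterized contours bit-exactly; slices outside the key range stay empty.
For concentric circles this interpolates the radius linearly, and for any
cone-frustum (linearly tapered) shape it is exact up to rasterization. On
profiles with curvature the chord between key slices under- or over-shoots;
with keys every 10 mm on a spindle-shaped tumor this contributes a few
percent of systematic volume underestimate — visible in the simulated
study, where semiautomatic volumes run ~5% below truth while manual runs
slightly above, the same direction as the clinical means (42 vs 46 ml).
Interpolation is done at the native pixel grid without supersampling; the
geometric tolerances used in the tests (one pixel at the interpolated
boundary, 1–2% on volumes) absorb the resulting one-pixel boundary error.

The HU window is applied only in the semiautomatic path, after
interpolation, with inclusive bounds (default `[0, 1000]`): air (−1000 HU)
inside the drawn outer boundary — the esophageal lumen — is removed, while
all soft tissue (tumor ≈ 40–70 HU) is untouched. Inclusivity maximizes
tissue inclusion and is irrelevant for soft tissue either way. Manual
segmentation deliberately applies no window: it is the reference workflow
in which the reader's contour is taken literally. Masks are immutable
values; the review step is modeled by `edit_mask`, a pure function whose
add/remove operations are appended to a replayable provenance list.

## Volumetry

`volume_from_mask` is the summation-of-area rule: per-slice set-pixel count
× pixel area × slice thickness, summed and reported in ml. This equals
total voxel count × voxel volume algebraically; both the per-slice and the
per-area (`volume_from_areas`) formulations are exposed because published
work reports areas as often as masks. Volumes keep full precision
internally; comparisons against integer-ml published tables round half away
from zero at presentation only.

## Agreement statistics

All statistics are computed from the two-rater ANOVA mean squares (rows =
subjects, columns = raters): `ICC(1,1) = (MSR−MSW)/(MSR+MSW)`,
`ICC(3,1) = (MSR−MSE)/(MSR+MSE)` and
`ICC(2,1) = (MSR−MSE)/(MSR+MSE+2(MSC−MSE)/n)` for k = 2, with
F-distribution confidence intervals (Satterthwaite degrees of freedom for
the agreement form). Degenerate inputs (zero total variance, zero
denominators) raise an explicit undefined-statistic error rather than
returning NaN. A caution surfaced by property testing: the familiar
ordering "agreement ≤ consistency" holds only when the rater variance
component is nonnegative (MSC ≥ MSE) and the common numerator is
nonnegative; the tests assert it under exactly those conditions.

Bland–Altman limits use the sample (n−1) SD and the 1.96 multiplier, so
width ≡ 3.92·SD(differences). The absolute percentage difference from the
mean is `100·|v₁−v₂|/(v₁+v₂)` per item — identical for either rater — with
a t-based CI for the mean (small n makes the normal approximation
inappropriate, and the source studies do not state their CI method).
Fisher's r-to-z comparison uses the standard independent-samples form;
p-values are reported at full precision and compared against published
bounds only.

## Study reproduction

The packaged measurement table (23 patients × 2 methods × 2 observers × 2
phases, integer ml) is transcribed from the published study and gated at
load time on the published per-column means and the 15/8
adenocarcinoma/squamous histology split — a transcription error fails
loudly, naming the offending column. Two aggregation questions are not
answerable from the publication: the ICC form, and whether the two contrast
phases entered the interobserver analysis as separate items (46 pairs) or
phase-averaged (23 pairs). `headline_stats` therefore computes all six
variants, each labelled with its form and pooling. The variant that
reproduces every published ICC to two decimals is two-way random effects,
absolute agreement, single measures, phases pooled; it is reported as the
headline and used by `scripts/acceptance.py`. Two published numbers are
contradicted by recomputation from the published table itself and are
flagged in the report: the abstract's 24% manual percentage difference
(the results section's 32% is what the table yields, 31.8%) and the 0.63
squamous-manual ICC (the table yields 0.64). The published Bland–Altman
widths (56.8/40.1 ml) recompute to 56.6/40.5 ml from the integer-ml table;
the 0.2–0.4 ml gap is consistent with the original analysis using
full-precision volumes, so width comparisons are made at 0.5 ml.

## Phantom and observer simulation

The phantom is a tube with per-slice outer (and optional lumen) radius,
linearly interpolated between slice centers, rendered as tumor tissue
(60 ± 15 HU) against mediastinal background (20 HU) with additive 10 HU
acquisition noise and −1000 HU lumen air; all levels are configuration, not
claims about tissue. Ground truth is the set of pixel centers inside the
outer and outside the lumen radius, and the reference volume is the exact
annulus-area integral — rasterized volume converges to it as spacing
shrinks. Observers outline the outer boundary only; in the semiautomatic
path the HU window is what removes the lumen, as at a workstation.

Observer tracing error is a smooth periodic Gaussian field over vertex
angle (truncated Fourier series, harmonics 0–8, squared-exponential
spectrum with angular scale 0.8 rad, pointwise SD = `boundary_sd`);
i.i.d. vertex noise would create self-intersecting polygons, smooth noise
mimics a human hand. The field is truncated at 3.5σ and at half the local
radius — tracing error on a small structure is proportionally small, and a
drawn region cannot invert. Extent error shifts the first and last
delineated slice independently by rounded N(0, `extent_sd`) slices;
beyond the true extent the end shape is reused.

Default study conditions: 23 patients, spindle-shaped tumors (length
30–80 mm, peak radius 8–20 mm, tapering to 2.5 mm) generated at 0.625 mm
and read at 2.5 mm on a 48–52 px, 1.25 mm in-plane grid — sizes chosen so
the full 100-study experiment is a routine desk computation; two contrast
phases are independent CT-noise and observer-noise realizations of the same
anatomy, making them honest intraobserver replicates. Manual observers
trace every slice independently with `boundary_sd` = 2.5 mm; semiautomatic
observers trace every 4th slice (plus both ends) with 0.6 mm. The asymmetry
is the modeled mechanism, and a modeling choice: a handful of deliberately
chosen, carefully drawn key slices versus quick tracing of ~25 thin slices.
It matters because the arithmetic alone goes the other way — linear
interpolation between noisy keys correlates the per-slice errors, so with
*equal* noise the sparse protocol would have about `step`-fold *larger*
volume-error variance than dense tracing. Only lower per-contour noise on
key slices (standardization by the threshold, fewer and more deliberate
decisions) produces the clinically observed ordering; the simulation
encodes that hypothesis explicitly.

What the simulation does and does not show: simulated interobserver ICCs
(≈0.98 manual vs ≈0.995 semiautomatic) are far higher than clinical ones
(0.56 vs 0.86) because the phantom omits the dominant clinical error
source — interpretation ambiguity of low-contrast boundaries and
gastro-esophageal junction anatomy, which is a per-reader-per-tumor
systematic effect, not tracing jitter. Passing the direction-of-effect test
(semiautomatic ICC > manual ICC in ≥95 of 100 studies) therefore supports
the mechanism's sign, not its clinical magnitude, and ICC magnitudes are
deliberately not acceptance-bearing.

## Known limitations

- Single region per slice; multi-focal tumors are out of scope.
- No DICOM series reading; NIfTI-1 and NRRD only.
- Shape-based interpolation is a documented stand-in for whatever the
  original proprietary workstation software did; no claim of equivalence.
- The Bland–Altman implementation does not correct for repeated measures
  per patient when phases are pooled, matching the source analyses.
- Invalid spacing metadata is guarded against but hard to exercise through
  nibabel/ITK, which sanitize such headers on read.
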