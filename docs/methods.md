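# Methods

## The measurement model

The C2–C7 sagittal Cobb angle is defined on the midsagittal plane as the
angle between the extension lines of the C2 and C7 inferior endplates. The
package works in a fixed 2-D frame — anterior = +x, superior = +y, physical
millimetres — and represents each endplate as a line with a canonical unit
direction (anterior component ≥ 0; if zero, superior component > 0). A
line's *inclination* is `atan2(superior, anterior)` of that direction, in
(−90°, 90°]; the Cobb angle is

```
cobb = inclination(C2 line) − inclination(C7 line),  wrapped to (−90°, 90°]
```

**Sign convention.** Lordosis — the C2 inferior endplate inclined
superior-anteriorly relative to C7's — is positive. The convention is
self-consistent across the phantom ground truth, both estimators and all
reports; the wrap keeps `cobb(a, b) = −cobb(b, a)` exact.

### Four-points estimator

Each endplate line is the chord LC2/LC7 through the detected bottom-anterior
and bottom-posterior corners. Two points per endplate means corner noise
propagates directly: for corner noise of standard deviation σ on a chord of
length W the angle noise per line is about `√2 σ / W` radians.

### Line-fitting estimator

Point sets PC2/PC7 are sampled along the inferior boundary of the
segmentation between the corners — every boundary-pixel column contributes
its most inferior pixel, the densest deterministic choice — and lines
DC2/DC7 are fitted by **orthogonal-distance (total) least squares**: the
line through the centroid along the principal axis of the points' scatter.
Orthogonal rather than vertical-offset regression was chosen because it is
equivariant under in-plane rotation, so the estimator does not depend on
patient positioning in the plane. The corners only delimit the edge span,
so corner noise enters weakly, and a symmetric endplate bulge shifts the fit
parallel to itself without tilting it — both reasons the line-fitting
estimator has the smaller error on curved, noisy endplates.

Supplied corners are snapped to the nearest boundary pixel before sampling;
corners farther than 6 mm from the boundary are rejected. The tolerance is
generous enough for realistic reader or detector scatter (inter-reader
outlier fences are a few mm) while still catching grossly misplaced points.

## Midsagittal selection

The midsagittal position is operationalized as the sagittal slice with the
largest C2 cross-sectional area, computed by voxel counting (count ×
in-plane voxel area). Counting matches the mask input, is exactly testable,
and needs no sub-voxel contouring. Ties go to the smallest slice index — an
arbitrary but documented rule; selection is by construction a global argmax
and unaffected by the labels of other vertebrae.

## Corner detection

The detector is a deterministic geometric stand-in satisfying the same
output contract as a trained key-point model (and replaceable by one via the
`CornerDetector` protocol). The bottom-anterior corner of a vertebra region
is the boundary-pixel extreme of the 45° support direction
"inferior + anterior" (maximize `a − s`); the bottom-posterior corner the
extreme of "inferior + posterior". These supports identify the corners of
bodies tilted up to ±45°.

On rasterized masks a fixed 45° support suffers *raster slip*: when the
endplate tilt approaches ±30° the support level lines run nearly parallel to
the bottom edge and half-pixel boundary noise can slide the argmax a pixel
or two along it. The detector therefore runs a second pass: the inferior
boundary profile between the first-pass corners is fitted by total least
squares, and the supports are re-applied rotated by the fitted edge
inclination. In the edge frame the slip geometry is the benign zero-tilt
case; measured worst-case corner error on noise-free phantoms is then under
half a voxel diagonal across tilts in [−30°, 30°] (the fixed-support single
pass reaches ~1.2 diagonals at ±30°). Ties break to the most inferior, then
most extreme anterior/posterior pixel. Regions touching the image border
yield a warning flag, since the true corner may be cropped.

## Annotation reconciliation

Two readers annotate every case; a third adjudicates. Per landmark, the
inter-reader distance is gated by a Tukey upper fence fitted on a training
pool:

```
Tp = Q3 + 1.5 × (Q3 − Q1)
```

with quartiles computed by linear interpolation of order statistics (the
common "type-7" estimator — the fence formula alone does not pin down a
quartile method, so one reproducible choice is fixed and tested against a
brute-force order-statistics oracle). A point is *reliable* iff its distance
is **strictly** less than Tp; a distance exactly at the fence is unreliable.
Unreliable landmarks are resolved per landmark independently: among the
three reader pairs the one with the smallest distance wins and the midpoint
of its two points becomes the final key point; distance ties break on the
lexicographically smallest reader-id pair. Paired Cobb readings are
reconciled the same way with an angle fence Tcobb — strictly-smaller
differences take the two readings' mean, others go to the third reader.

## Agreement statistics

* **PCK** — per landmark, the fraction of predictions strictly within that
  landmark's fence; exactly at the fence counts as incorrect, mirroring the
  reliability rule. PCK is non-decreasing in the fence by construction.
* **Matched-samples t test** — `p > 0.05` read as "no significant
  difference". Identical lists give t = 0, p = 1; constant nonzero
  differences leave t undefined and are flagged rather than fabricated.
* **ICC** — two-way random effects, absolute agreement, single measures
  (ICC(2,1)), computed via `pingouin.intraclass_corr` with the degenerate
  exact-equality case (zero residual mean square) handled explicitly as
  ICC = 1. Absolute agreement was chosen over consistency because method
  comparison should penalize systematic bias, matching the Bland–Altman
  framing; the implementation is verified against a from-scratch
  variance-components computation on a fixed worked set. Bands: < 0.4 poor,
  0.4–0.6 general, 0.6–0.75 good, ≥ 0.75 excellent.
* **Pearson r** — with a Fisher-z 95% CI. Bands on |r|: < 0.4 weak,
  0.4–0.6 moderate, 0.6–0.8 strong, ≥ 0.8 extremely strong. The moderate
  band fills a gap the conventional banding leaves open and is labeled as an
  extension.
* **MAE** — `(1/n) Σ |observed − predicted|` with a seeded percentile
  bootstrap 95% CI (2000 resamples; no closed form is standard for MAE).
* **Bland–Altman** — mean difference, SD of differences (n−1), and
  LoA = mean ± 1.96 SD, plus a per-case (mean, difference) table for
  plotting.

## The phantom generator

The phantom emulates the statistical structure the pipeline assumes — *not*
vertebral anatomy. Six labeled bodies (C2–C7) are rendered as quadrilateral
prisms stacked along the superior–inferior axis; only the inferior-edge
geometry that the estimators consume is controllable:

| parameter | meaning | default |
|---|---|---|
| `c2_tilt_deg`, `c7_tilt_deg` | endplate inclinations; their difference is the exact truth angle | — |
| `endplate_curvature` | sagitta/chord of a circular arc bulging inferiorly | 0 |
| `osteophyte_size_mm` | length of triangular corner protrusions | 0 |
| `corner_jitter_sd_mm` | isotropic Gaussian reader noise on landmarks | 0 |
| `voxel_spacing_mm` | (LR, AP, SI) spacing | (1.0, 0.15, 0.15) |
| `n_slices` | sagittal slice count | 9 |
| `in_plane_rotation_deg` | rigid rotation of the whole scene | 0 |

Design choices:

* **Endplate chord 36 mm, in-plane spacing 0.15 mm.** The chord is kept long
  and the raster fine so that half-voxel corner quantization perturbs a
  chord's inclination by far less than the 0.5° raster tolerance used
  throughout (atan(0.21/36) ≈ 0.3° worst case, typically much less).
* **Curvature as a circular arc** bulging inferiorly: a single parameter
  reproduces the "lower edge is not a straight line" condition that
  separates the two estimators, and its symmetric shape gives an exact
  oracle (the fitted line parallels the chord).
* **Osteophytes as triangular corner spikes** pointing inferior-outward:
  the minimal shape that reproduces the known corner-detection failure mode
  of marginal bony outgrowths.
* **Reader jitter isotropic Gaussian in mm** — the simplest noise model
  compatible with mm-scale outlier fences.
* **C2 area profile.** C2 is rendered full-size only at the designated
  middle slice and shrunk linearly (8% per slice) on either side, so
  maximal-area midsagittal selection has a strict, known argmax.
* **Cohort preset.** Target angles are drawn Normal(0.50°, 12.83°) — a
  clinically plausible cervical population spread — clipped to ±38° so each
  endplate tilt stays inside the detector's validity range; per-case seeds
  derive deterministically from the cohort seed.
* **Rasterization is closed**: polygon interiors plus the nearest pixels
  along the outline, so corner apices always own a pixel within half a
  voxel diagonal.

What the phantom does **not** model: CT intensities (it is a label mask, as
the pipeline consumes segmentations), soft tissue, vertebral micro-anatomy,
inter-vertebral pose variation beyond the tilt interpolation, and
non-Gaussian reader behaviour. Passing tests therefore demonstrate the
geometric and statistical correctness of the pipeline on its input contract,
not segmentation quality on real CT.

## Numerical choices and degenerate inputs

* Angles are reported in degrees, serialized with at least 4 decimals,
  normalized to (−90°, 90°]; the wrap is implemented branch-wise so
  antisymmetry is bit-exact.
* TLS fits reject identical points and isotropic scatter (no unique
  principal axis, relative singular-value gap < 1e-9).
* Coincident endplate corners, missing vertebra labels, zero/negative
  spacings, non-integer label images and malformed landmark files raise
  distinct, named validation errors.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the same spec and seed reproduce a
  byte-identical case, and the CLI logs a configuration hash and seed per
  run.
* Validation problem sizes: exact-recovery sweeps use 7 targets spanning
  ±30°; the estimator-separation study uses 100-case cohorts over 5 seeds
  with sagitta/chord 0.04 and 0.7 mm jitter; oracle checks use 50 random
  5-point sets (grid search at 1e-3 rad) and the exhaustive 840
  small-integer lists of length 4–6 for the fence.

## Known limitations

* The geometric corner detector presumes endplate tilts within ±45° (first
  pass) and benefits from the two-pass refinement only when the inferior
  edge dominates the boundary profile; pathological masks (e.g. heavily
  osteophytic corners) deliberately mislead it, as they do trained
  detectors.
* The midsagittal rule inherits any C2 segmentation error; no oblique
  reformatting is attempted.
* The line-fitting edge sampler takes one point per boundary column and so
  assumes the inferior edge is a function of the anterior coordinate
  (|tilt| < 45°).
* No DICOM input, no X-ray projections, and no alternative curvature
  indices (C1–C7 angle, T1 slope, SVA).
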