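# cervcobb

Automatic measurement of the **C2–C7 sagittal Cobb angle** on cervical-spine
CT segmentations, for researchers building or validating quantitative spine
pipelines.

The sagittal Cobb angle — the angle between the extension lines of the C2 and
C7 inferior vertebral endplates in the midsagittal plane — is the standard
index of cervical lordosis/kyphosis. Manual measurement is slow and
subjective; this package implements the automatic pipeline end to end:

1. **Midsagittal selection** — among the sagittal slices of a labeled
   C2–C7 segmentation volume, pick the one with the largest C2
   cross-sectional area.
2. **Corner detection** — locate the bottom-anterior and bottom-posterior
   corners of the C2 and C7 bodies with a deterministic two-pass 45°-support
   operator (a pluggable stand-in with the same output contract as a trained
   key-point model).
3. **Angle estimation**, two ways:
   * *four-points*: connect each endplate's corners into chords LC2 and LC7;
     the angle between them is the Cobb angle;
   * *line-fitting*: sample point sets PC2 and PC7 along each inferior edge
     between the corners and fit total-least-squares lines DC2 and DC7; the
     angle between the fits is the Cobb angle.  When endplates are curved or
     corners are noisy, the fit averages the error out and beats the chords.
4. **Annotation reconciliation** — gate two readers' landmarks by per-landmark
   Tukey fences `Tp = Q3 + 1.5 (Q3 − Q1)` on their distances (and paired
   angle readings by an analogous fence `Tcobb`); adjudicate outliers with a
   third reader, keeping the midpoint of the closest pair.
5. **Agreement statistics** — PCK against the fences, matched-samples *t*
   test, ICC(2,1) with interpretation bands, Pearson *r* with Fisher-z CI,
   MAE with a bootstrap CI, and Bland–Altman 95% limits of agreement.

Because no clinical volumes ship with the package, a **synthetic phantom
generator** renders labeled C2–C7 stacks whose endplate tilts (hence the
exact ground-truth angle), endplate convexity, corner osteophytes and reader
jitter are all controllable — every stage of the pipeline is validated
against known truth.

## Worked example

```python
import cervcobb as cc

# a phantom with a known 20 degree lordosis, curved endplates, reader noise
spec = cc.PhantomSpec.from_target(
    20.0, endplate_curvature=0.04, corner_jitter_sd_mm=0.7, rng_seed=1
)
case = cc.generate_case(spec, "demo")

idx, slc = cc.select_midsagittal(case.volume)
lm = cc.detect_corners(slc, "demo")
fp = cc.measure_four_points(case.reader_landmarks[0])
lf = cc.measure_line_fitting(slc, case.reader_landmarks[0])
print(f"truth {case.truth_cobb_deg:.4f}")
print(f"four-points  {fp.angle_deg:.4f}")
print(f"line-fitting {lf.angle_deg:.4f}")
```

prints

```
truth 20.0000
four-points  22.1822
line-fitting 19.9072
```

— with 0.7 mm corner jitter the four-points chord is off by over two degrees,
while the line fit over ~240 edge points stays within 0.1°: the separation
between the two estimators that motivates using line fitting on real scans.

The same pipeline is available from the shell:

```sh
cervcobb simulate --n 5 --seed 1 --out cohort/
cervcobb measure cohort/*.nii.gz --method both --out measured.csv
cervcobb evaluate --pred measured.csv --pred-method line_fitting \
    --ref cohort_ref.csv --fence fence.json --out-prefix eval
cervcobb reconcile --annotations readers.json --out reconciliation.csv
```

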