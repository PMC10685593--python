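"""Synthetic labeled cervical-spine phantoms with known ground-truth angles.

The phantom emulates the statistical structure the measurement pipeline
assumes, not vertebral anatomy: six labeled bodies (C2–C7) rendered as
rounded quadrilateral prisms stacked along the superior–inferior axis, whose
C2 and C7 inferior edges have

* controllable inclination — their signed difference is the exact
  ground-truth Cobb angle;
* controllable convexity — a circular arc bulging inferiorly with a given
  sagitta-to-chord ratio, emulating endplates whose lower edge is not a
  straight line (the condition that separates the four-points and
  line-fitting estimators);
* optional osteophyte-like triangular protrusions at the corner apices,
  emulating the bony outgrowths that defeat corner detection;

plus two simulated readers whose landmarks are the true corners with
independent isotropic Gaussian jitter (in mm, seeded).

The C2 body is rendered full-size only at a designated sagittal slice and
shrunk on either side, so maximal-C2-area midsagittal selection has a known
correct answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon
from skimage.draw import polygon_perimeter as _draw_perimeter

from .volume_io import (
    ROLE_AP,
    ROLE_LR,
    ROLE_SI,
    LabelVolume,
    LandmarkSet,
    ValidationError,
    write_label_volume,
    write_landmarks,
)

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_case",
    "generate_cohort",
    "cohort_specs",
    "write_case",
    "write_cohort",
]

# Body geometry (mm).  Realism is not a goal; the endplate chord is kept long
# (36 mm) so that half-voxel corner quantization perturbs the chord
# inclination by well under the raster tolerance.
BODY_WIDTH_MM = 36.0
BODY_HEIGHT_MM = 14.0
VERTEBRA_PITCH_MM = 20.0
CANVAS_MARGIN_MM = 4.0

VERTEBRAE = ("C2", "C3", "C4", "C5", "C6", "C7")
LABEL_MAP = {name: i + 2 for i, name in enumerate(VERTEBRAE)}

#: Per-slice linear shrink applied to C2 away from the designated midsagittal
#: slice; guarantees a strict area maximum there.
C2_SHRINK_PER_SLICE = 0.08


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case.

    The ground-truth Cobb angle is ``c2_tilt_deg − c7_tilt_deg`` by the
    package's sign convention (lordosis positive); it is exposed as
    :attr:`target_cobb_deg` so the invariant holds by construction.
    """

    c2_tilt_deg: float
    c7_tilt_deg: float
    endplate_curvature: float = 0.0  # sagitta / chord, >= 0; 0 = straight edge
    osteophyte_size_mm: float = 0.0
    corner_jitter_sd_mm: float = 0.0
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 0.15, 0.15)  # (LR, AP, SI)
    n_slices: int = 9
    rng_seed: int = 0
    in_plane_rotation_deg: float = 0.0  # rigid rotation of the whole phantom

    def __post_init__(self) -> None:
        for name in ("c2_tilt_deg", "c7_tilt_deg"):
            v = getattr(self, name)
            if not (math.isfinite(v) and abs(v) < 45.0):
                raise ValidationError(f"{name} must be finite and within (-45, 45)")
        for name in ("endplate_curvature", "osteophyte_size_mm", "corner_jitter_sd_mm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValidationError("voxel_spacing_mm must be three strictly positive values")
        if self.n_slices < 3:
            raise ValidationError("n_slices must be >= 3")

    @property
    def target_cobb_deg(self) -> float:
        return self.c2_tilt_deg - self.c7_tilt_deg

    @classmethod
    def from_target(cls, target_cobb_deg: float, **kwargs) -> "PhantomSpec":
        """Split a target angle symmetrically between the C2 and C7 tilts."""
        return cls(
            c2_tilt_deg=target_cobb_deg / 2.0,
            c7_tilt_deg=-target_cobb_deg / 2.0,
            **kwargs,
        )


@dataclass
class PhantomCase:
    """A generated case: volume, truth, and two simulated readers."""

    case_id: str
    spec: PhantomSpec
    volume: LabelVolume
    midsagittal_index: int
    truth_landmarks: LandmarkSet
    truth_cobb_deg: float
    reader_landmarks: tuple[LandmarkSet, LandmarkSet]


def _rot(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s], [s, c]])


def _arc_points(p0: np.ndarray, p1: np.ndarray, sagitta: float, bulge: np.ndarray,
                step_mm: float = 0.4) -> np.ndarray:
    """Circular arc from p0 to p1 bulging by `sagitta` along the unit `bulge`."""
    chord = float(np.linalg.norm(p1 - p0))
    if sagitta <= 0 or chord == 0:
        return np.stack([p0, p1])
    radius = (chord * chord / 4.0 + sagitta * sagitta) / (2.0 * sagitta)
    mid = 0.5 * (p0 + p1)
    center = mid - bulge * (radius - sagitta)
    a0 = math.atan2(*(p0 - center)[::-1])
    a1 = math.atan2(*(p1 - center)[::-1])
    # take the arc passing through the bulge apex (the short way round)
    if abs(a1 - a0) > math.pi:
        a1 += 2.0 * math.pi * (1 if a1 < a0 else -1)
    n = max(8, int(abs(a1 - a0) * radius / step_mm))
    ang = np.linspace(a0, a1, n)
    return center + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _vertebra_polygons(spec: PhantomSpec, index: int) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    """Untranslated polygons (body + osteophytes) and exact bottom corners.

    Geometry lives in an (anterior, superior) mm frame centred on the column;
    the caller translates everything into the positive quadrant afterwards.
    """
    tilt = np.interp(index, [0, len(VERTEBRAE) - 1], [spec.c2_tilt_deg, spec.c7_tilt_deg])
    theta = tilt + spec.in_plane_rotation_deg
    d = np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta))])
    n_sup = np.array([-d[1], d[0]])  # superior-pointing edge normal
    mid = np.array([0.0, (len(VERTEBRAE) - 1 - index) * VERTEBRA_PITCH_MM])
    if spec.in_plane_rotation_deg:
        pivot = np.array([0.0, (len(VERTEBRAE) - 1) * VERTEBRA_PITCH_MM / 2.0])
        mid = pivot + _rot(spec.in_plane_rotation_deg) @ (mid - pivot)

    half = BODY_WIDTH_MM / 2.0
    p_post = mid - half * d
    p_ant = mid + half * d
    bottom = _arc_points(
        p_post, p_ant, spec.endplate_curvature * BODY_WIDTH_MM, bulge=-n_sup
    )
    body = np.vstack(
        [bottom, [p_ant + BODY_HEIGHT_MM * n_sup, p_post + BODY_HEIGHT_MM * n_sup]]
    )
    polys = [body]
    if spec.osteophyte_size_mm > 0:
        L = spec.osteophyte_size_mm
        for corner, outward in ((p_ant, d), (p_post, -d)):
            apex_dir = outward - n_sup
            apex_dir = apex_dir / np.linalg.norm(apex_dir)
            polys.append(
                np.stack([corner - 3.0 * outward, corner + 3.0 * n_sup, corner + L * apex_dir])
            )
    return polys, {"ant": p_ant, "post": p_post}


def _scale_about(poly: np.ndarray, center: np.ndarray, f: float) -> np.ndarray:
    return center + f * (poly - center)


def generate_case(spec: PhantomSpec, case_id: str = "case000") -> PhantomCase:
    """Render one phantom case: label volume, truth landmarks, reader jitter.

    The volume axes are ordered (left-right, anterior-posterior,
    superior-inferior); all randomness comes from ``spec.rng_seed``, so the
    same spec yields a byte-identical case.
    """
    sp_lr, sp_a, sp_s = spec.voxel_spacing_mm
    per_vertebra = [_vertebra_polygons(spec, i) for i in range(len(VERTEBRAE))]

    # translate the whole scene into the positive quadrant with a margin
    all_pts = np.vstack([p for polys, _ in per_vertebra for p in polys])
    shift = CANVAS_MARGIN_MM - all_pts.min(axis=0)
    extent = all_pts.max(axis=0) - all_pts.min(axis=0) + 2 * CANVAS_MARGIN_MM
    n_a = int(math.ceil(extent[0] / sp_a)) + 1
    n_s = int(math.ceil(extent[1] / sp_s)) + 1

    mid_slice = spec.n_slices // 2
    labels = np.zeros((spec.n_slices, n_a, n_s), dtype=np.int16)

    def _fill(plane: np.ndarray, poly: np.ndarray, value: int) -> None:
        # closed rasterization: interior plus the nearest pixels along the
        # outline, so corner apices always own a pixel within half a diagonal
        r, c = poly[:, 0] / sp_a, poly[:, 1] / sp_s
        rr, cc = _draw_polygon(r, c, plane.shape)
        plane[rr, cc] = value
        rr, cc = _draw_perimeter(r, c, plane.shape, clip=True)
        plane[rr, cc] = value

    # C3..C7 are identical on every slice; render once and broadcast
    base = np.zeros((n_a, n_s), dtype=np.int16)
    for i, name in reversed(list(enumerate(VERTEBRAE))):
        if name == "C2":
            continue
        for poly in per_vertebra[i][0]:
            _fill(base, poly + shift, LABEL_MAP[name])
    labels[:] = base

    # C2 shrinks linearly away from the designated midsagittal slice
    c2_polys, c2_corners = per_vertebra[0]
    c2_center = 0.5 * (c2_corners["ant"] + c2_corners["post"]) + shift
    for k in range(spec.n_slices):
        f = max(0.3, 1.0 - C2_SHRINK_PER_SLICE * abs(k - mid_slice))
        for poly in c2_polys:
            _fill(labels[k], _scale_about(poly + shift, c2_center, f), LABEL_MAP["C2"])

    volume = LabelVolume(
        labels=labels,
        spacing_mm=(sp_lr, sp_a, sp_s),
        axis_roles={0: ROLE_LR, 1: ROLE_AP, 2: ROLE_SI},
        label_map=dict(LABEL_MAP),
    )

    c7_corners = per_vertebra[-1][1]
    truth_points = {
        "C2_ant": c2_corners["ant"] + shift,
        "C2_post": c2_corners["post"] + shift,
        "C7_ant": c7_corners["ant"] + shift,
        "C7_post": c7_corners["post"] + shift,
    }
    truth = LandmarkSet(case_id=case_id, reader_id="truth", points=truth_points)

    rng = np.random.default_rng(spec.rng_seed)
    readers = []
    for reader_id in ("reader1", "reader2"):
        pts = {
            name: truth_points[name] + rng.normal(0.0, spec.corner_jitter_sd_mm, size=2)
            for name in truth_points
        }
        readers.append(LandmarkSet(case_id=case_id, reader_id=reader_id, points=pts))

    return PhantomCase(
        case_id=case_id,
        spec=spec,
        volume=volume,
        midsagittal_index=mid_slice,
        truth_landmarks=truth,
        truth_cobb_deg=spec.target_cobb_deg,
        reader_landmarks=(readers[0], readers[1]),
    )


def generate_cohort(specs: list[PhantomSpec], case_ids: list[str] | None = None) -> list[PhantomCase]:
    """One case per spec, order preserved; each spec carries its own seed."""
    if not specs:
        raise ValidationError("empty spec list")
    if case_ids is None:
        case_ids = [f"case{i:03d}" for i in range(len(specs))]
    if len(case_ids) != len(specs):
        raise ValidationError("case_ids must match specs in length")
    return [generate_case(s, cid) for s, cid in zip(specs, case_ids)]


def cohort_specs(
    n: int,
    seed: int,
    angle_mean_deg: float = 0.50,
    angle_sd_deg: float = 12.83,
    endplate_curvature: float = 0.0,
    osteophyte_size_mm: float = 0.0,
    corner_jitter_sd_mm: float = 0.0,
    **kwargs,
) -> list[PhantomSpec]:
    """Draw a cohort of specs with Gaussian-distributed target angles.

    Defaults emulate a clinically plausible cervical population
    (0.50 ± 12.83° reference-standard Cobb angles); targets are clipped to
    ±38° so both tilts stay inside the detector's validity range.  Per-case
    seeds derive deterministically from ``seed``.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    targets = np.clip(rng.normal(angle_mean_deg, angle_sd_deg, size=n), -38.0, 38.0)
    case_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        PhantomSpec.from_target(
            float(t),
            endplate_curvature=endplate_curvature,
            osteophyte_size_mm=osteophyte_size_mm,
            corner_jitter_sd_mm=corner_jitter_sd_mm,
            rng_seed=int(s),
            **kwargs,
        )
        for t, s in zip(targets, case_seeds)
    ]


def write_case(case: PhantomCase, outdir: str | Path) -> dict[str, Path]:
    """Write one case: NIfTI volume + landmark JSON (truth and both readers)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vol_path = write_label_volume(case.volume, outdir / f"{case.case_id}.nii.gz")
    lm_path = write_landmarks(
        [case.truth_landmarks, *case.reader_landmarks],
        outdir / f"{case.case_id}_landmarks.json",
    )
    return {"volume": vol_path, "landmarks": lm_path}


def write_cohort(cases: list[PhantomCase], outdir: str | Path) -> Path:
    """Write all cases plus a manifest CSV (case id, truth angle, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        write_case(case, outdir)
    manifest = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "truth_cobb_deg": [c.truth_cobb_deg for c in cases],
            "seed": [c.spec.rng_seed for c in cases],
        }
    )
    path = outdir / "manifest.csv"
    manifest.to_csv(path, index=False, float_format="%.6f")
    return path
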