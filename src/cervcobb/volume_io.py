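"""Containers and file formats for the Cobb-angle pipeline.

Conventions (fixed package-wide):

* Landmark and in-plane coordinates are **physical millimetres**, never voxel
  indices, so that distance thresholds are comparable across voxel spacings.
* The midsagittal plane uses a right-handed 2-D frame with **anterior = +first
  axis** and **superior = +second axis**; grid indexing is 0-based and the
  physical coordinate of a pixel is ``index * spacing``.
* Volumes are 3-D integer label grids whose axes carry anatomical roles
  (left-right, anterior-posterior, superior-inferior).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ROLE_LR",
    "ROLE_AP",
    "ROLE_SI",
    "LANDMARK_NAMES",
    "ValidationError",
    "NonIntegerLabelError",
    "SpacingError",
    "LabelVolume",
    "SagittalSlice",
    "LandmarkSet",
    "read_label_volume",
    "write_label_volume",
    "read_landmarks",
    "write_landmarks",
    "read_measurements",
    "write_measurements",
]

ROLE_LR = "left-right"
ROLE_AP = "anterior-posterior"
ROLE_SI = "superior-inferior"
_ROLES = (ROLE_LR, ROLE_AP, ROLE_SI)

#: The four endplate-corner landmarks the pipeline measures.
LANDMARK_NAMES = ("C2_ant", "C2_post", "C7_ant", "C7_post")

_LANDMARK_SCHEMA = "cervcobb-landmarks-v1"


class ValidationError(ValueError):
    """A container or file violates one of its documented invariants."""


class NonIntegerLabelError(ValidationError):
    """A label image holds floating-point voxel data."""


class SpacingError(ValidationError):
    """A voxel spacing entry is missing, zero or negative."""


@dataclass
class LabelVolume:
    """3-D integer label grid with physical spacing and anatomical axis roles.

    Parameters
    ----------
    labels : ndarray of int, 3-D
        Voxel labels; 0 is background.
    spacing_mm : tuple of 3 floats
        Per-axis voxel spacing in mm, strictly positive.
    axis_roles : dict
        Bijection from grid-axis index {0, 1, 2} onto the anatomical roles
        ``left-right``, ``anterior-posterior``, ``superior-inferior``.
    label_map : dict
        Vertebra name -> integer label; must cover at least ``C2`` and ``C7``.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    axis_roles: dict[int, str]
    label_map: dict[str, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise NonIntegerLabelError("non-integer labels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3:
            raise SpacingError("spacing_mm must have three entries")
        for ax, s in enumerate(self.spacing_mm):
            if not (math.isfinite(s) and s > 0):
                raise SpacingError(f"non-positive spacing on axis {ax}")
        self.axis_roles = {int(k): str(v) for k, v in self.axis_roles.items()}
        if sorted(self.axis_roles) != [0, 1, 2] or set(self.axis_roles.values()) != set(_ROLES):
            raise ValidationError(
                "axis_roles must map axes {0,1,2} one-to-one onto "
                f"{_ROLES}, got {self.axis_roles}"
            )
        for name in ("C2", "C7"):
            if name not in self.label_map:
                raise ValidationError(f"label_map must contain {name}")

    def axis_of(self, role: str) -> int:
        """Grid axis carrying the given anatomical role."""
        for ax, r in self.axis_roles.items():
            if r == role:
                return ax
        raise ValidationError(f"no axis with role {role!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and self.axis_roles == other.axis_roles
            and self.label_map == other.label_map
        )


@dataclass
class SagittalSlice:
    """A 2-D label mask in the midsagittal frame (anterior, superior).

    ``labels[ia, is_]`` sits at physical position
    ``(ia * spacing_mm[0], is_ * spacing_mm[1])`` mm (anterior, superior).
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float]
    label_map: dict[str, int]
    index: int | None = None  # originating left-right slice index, if any

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("slice labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise NonIntegerLabelError("non-integer labels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        for ax, s in enumerate(self.spacing_mm):
            if not (math.isfinite(s) and s > 0):
                raise SpacingError(f"non-positive spacing on axis {ax}")


@dataclass
class LandmarkSet:
    """The four inferior-endplate corners for one case as seen by one reader.

    Points are 2-D (anterior, superior) physical coordinates in mm within the
    midsagittal plane.
    """

    case_id: str
    reader_id: str
    points: dict[str, np.ndarray]
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if set(self.points) != set(LANDMARK_NAMES):
            missing = sorted(set(LANDMARK_NAMES) - set(self.points))
            if missing:
                raise ValidationError(f"missing landmark {missing[0]}")
            extra = sorted(set(self.points) - set(LANDMARK_NAMES))
            raise ValidationError(f"unexpected landmark {extra[0]}")
        pts = {}
        for name in LANDMARK_NAMES:
            p = np.asarray(self.points[name], dtype=float)
            if p.shape != (2,):
                raise ValidationError(f"landmark {name} must be a 2-D point")
            if not np.all(np.isfinite(p)):
                raise ValidationError(f"non-finite coordinate for landmark {name}")
            pts[name] = p
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def with_points(self, points: dict[str, np.ndarray]) -> "LandmarkSet":
        return replace(self, points=points)

    def almost_equal(self, other: "LandmarkSet", tol_mm: float = 1e-9) -> bool:
        return all(
            np.allclose(self.points[n], other.points[n], atol=tol_mm)
            for n in LANDMARK_NAMES
        )


# ---------------------------------------------------------------------------
# NIfTI volumes (label grid + JSON sidecar carrying roles and the label map)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as NIfTI plus a JSON sidecar.

    The affine encodes the voxel spacing; the sidecar records the axis roles
    and the vertebra label map, which NIfTI itself cannot carry.
    """
    path = Path(path)
    affine = np.diag([*vol.spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.labels, dtype=np.int16), affine)
    nib.save(img, str(path))
    sidecar = {
        "axis_roles": {str(k): v for k, v in vol.axis_roles.items()},
        "label_map": vol.label_map,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_label_volume(path: str | Path, label_map: dict[str, int] | None = None) -> LabelVolume:
    """Read a NIfTI label image back into a :class:`LabelVolume`.

    The label map and axis roles come from the JSON sidecar written alongside,
    or from the ``label_map`` argument (axis roles then default to
    (LR, AP, SI) in grid-axis order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        raise NonIntegerLabelError(f"non-integer labels in {path}")
    zooms = img.header.get_zooms()[:3]
    for ax, z in enumerate(zooms):
        if not (math.isfinite(z) and z > 0):
            raise SpacingError(f"missing or zero spacing on axis {ax} in {path}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        axis_roles = {int(k): v for k, v in meta["axis_roles"].items()}
        lmap = meta["label_map"] if label_map is None else label_map
    else:
        if label_map is None:
            raise ValidationError(f"no sidecar and no label_map given for {path}")
        axis_roles = {0: ROLE_LR, 1: ROLE_AP, 2: ROLE_SI}
        lmap = label_map
    return LabelVolume(
        labels=data.astype(np.int16),
        spacing_mm=tuple(float(z) for z in zooms),
        axis_roles=axis_roles,
        label_map={str(k): int(v) for k, v in lmap.items()},
    )


# ---------------------------------------------------------------------------
# Landmark annotation files (JSON, physical mm)
# ---------------------------------------------------------------------------

def write_landmarks(sets: list[LandmarkSet], path: str | Path) -> Path:
    """Serialize landmark sets (one record per case x reader) as JSON."""
    path = Path(path)
    records = [
        {
            "case_id": s.case_id,
            "reader_id": s.reader_id,
            "points": {n: [float(v) for v in s.points[n]] for n in LANDMARK_NAMES},
        }
        for s in sets
    ]
    path.write_text(json.dumps({"schema": _LANDMARK_SCHEMA, "records": records}, indent=1))
    return path


def read_landmarks(path: str | Path) -> list[LandmarkSet]:
    """Read a landmark JSON file, validating the schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    doc = json.loads(path.read_text())
    if not isinstance(doc, dict) or "records" not in doc:
        raise ValidationError(f"not a landmark file: {path}")
    out = []
    for rec in doc["records"]:
        pts = rec.get("points", {})
        for name in LANDMARK_NAMES:
            if name not in pts:
                raise ValidationError(f"missing landmark {name} in {path}")
        out.append(
            LandmarkSet(
                case_id=str(rec["case_id"]),
                reader_id=str(rec["reader_id"]),
                points={n: np.asarray(pts[n], dtype=float) for n in LANDMARK_NAMES},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Measurement tables (CSV)
# ---------------------------------------------------------------------------

def write_measurements(rows: list, path: str | Path) -> Path:
    """Write Cobb measurements as CSV (case_id, method, angle_deg).

    Angles are serialized with 6 decimal places.
    """
    if not rows:
        raise ValidationError("empty measurement list")
    path = Path(path)
    df = pd.DataFrame(
        {
            "case_id": [r.case_id for r in rows],
            "method": [r.method for r in rows],
            "angle_deg": [r.angle_deg for r in rows],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV back into a DataFrame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such measurement table: {path}")
    df = pd.read_csv(path)
    required = {"case_id", "method", "angle_deg"}
    if not required.issubset(df.columns):
        raise ValidationError(f"measurement table missing columns {sorted(required - set(df.columns))}")
    return df
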