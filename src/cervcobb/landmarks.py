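"""Endplate-corner detection and multi-reader annotation reconciliation.

Corner detection
----------------
The four measurement landmarks are the bottom-anterior and bottom-posterior
corners of the C2 and C7 vertebral bodies on the midsagittal mask.  The
detector here is a deterministic geometric operator: on the vertebra region,
the bottom-anterior corner is the pixel extreme in the "inferior + anterior"
support direction (maximizing ``anterior − superior``) and the
bottom-posterior corner the extreme in "inferior + posterior" (maximizing
``−anterior − superior``).  These 45° support functions recover the corners
of bodies tilted by up to ±45° and are robust to the exact boundary
parametrization.  The detector satisfies the same output contract as a
trained key-point model and can be swapped for one via
:class:`CornerDetector`.

Reconciliation
--------------
Two readers annotate independently; per landmark, the inter-reader distance
is gated by a Tukey upper fence ``Tp = Q3 + 1.5 × (Q3 − Q1)`` computed on a
training pool of distances.  A point is *reliable* iff its distance is
strictly less than Tp; unreliable points are adjudicated by a third reader:
the pair of readers with the smallest distance wins, and the midpoint of
their two points becomes the final landmark.  The same scheme gates paired
Cobb-angle measurements with an angle fence (Tcobb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

from .volume_io import LANDMARK_NAMES, LandmarkSet, SagittalSlice, ValidationError

__all__ = [
    "OutlierFence",
    "CornerDetector",
    "detect_corners",
    "pairwise_distance",
    "fit_fence",
    "fit_fences",
    "classify_reliability",
    "adjudicate",
    "reconcile_measurements",
    "write_reconciliation_report",
]


@dataclass
class OutlierFence:
    """Per-landmark Tukey fences in mm, plus the angle fence Tcobb in degrees."""

    per_landmark_tp_mm: dict[str, float]
    tcobb_deg: float | None = None

    def __post_init__(self) -> None:
        for name, tp in self.per_landmark_tp_mm.items():
            if not tp > 0:
                raise ValidationError(f"fence for {name} must be strictly positive")
        if self.tcobb_deg is not None and not self.tcobb_deg > 0:
            raise ValidationError("tcobb_deg must be strictly positive")

    def tp(self, name: str) -> float:
        if name not in self.per_landmark_tp_mm:
            raise ValidationError(f"no fence for landmark {name}")
        return self.per_landmark_tp_mm[name]


class CornerDetector(Protocol):
    """Anything that maps a midsagittal mask to the four endplate corners.

    The default implementation is :func:`detect_corners`; a learned key-point
    model wrapping the same signature can be substituted.
    """

    def __call__(self, slc: SagittalSlice, case_id: str = ...) -> LandmarkSet: ...


def _extreme_corner(mm: np.ndarray, anterior_sign: float, tilt_deg: float = 0.0) -> np.ndarray:
    """Pixel maximizing the 45° corner support, optionally in a tilted frame.

    The support is ``anterior_sign * a' − s'`` in coordinates rotated by
    ``−tilt_deg`` (so the support direction follows the endplate).  Ties
    resolve to the most inferior, then most extreme anterior/posterior point.
    """
    c, s = math.cos(math.radians(tilt_deg)), math.sin(math.radians(tilt_deg))
    p = mm @ np.array([[c, -s], [s, c]])  # coordinates in the edge frame
    score = anterior_sign * p[:, 0] - p[:, 1]
    order = np.lexsort((-anterior_sign * p[:, 0], p[:, 1], -score))
    return mm[order[0]]


def _edge_tilt_deg(idx: np.ndarray, sp: np.ndarray, a_lo: int, a_hi: int) -> float:
    """Inclination of the inferior boundary profile between two columns.

    Total-least-squares direction of the per-column most-inferior pixels,
    in degrees within (−90, 90].
    """
    sel = (idx[:, 0] >= a_lo) & (idx[:, 0] <= a_hi)
    cols = idx[sel]
    if len(cols) == 0:
        return 0.0
    order = np.lexsort((cols[:, 1], cols[:, 0]))
    cols = cols[order]
    first = np.unique(cols[:, 0], return_index=True)[1]
    profile = cols[first] * sp  # most inferior pixel per column, in mm
    if len(profile) < 2:
        return 0.0
    centered = profile - profile.mean(axis=0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[0] == 0.0:
        return 0.0
    theta = math.degrees(math.atan2(vt[0, 1], vt[0, 0]))
    if theta > 90.0:
        theta -= 180.0
    elif theta <= -90.0:
        theta += 180.0
    return theta


def detect_corners(slc: SagittalSlice, case_id: str = "case") -> LandmarkSet:
    """Locate the four inferior-endplate corners on a midsagittal mask.

    Two deterministic passes per vertebra: a first pass finds the support
    extremes in the anatomical frame; a second pass re-applies the supports
    rotated by the inferior edge's fitted inclination, which removes the
    raster slip the fixed 45° supports suffer on strongly tilted endplates.
    If a vertebra region touches the image border the result carries a
    warning flag (the corner may be truncated).
    """
    points: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    sp = np.asarray(slc.spacing_mm)
    for vert in ("C2", "C7"):
        if vert not in slc.label_map:
            raise ValidationError(f"vertebra {vert} not in label map")
        mask = slc.labels == slc.label_map[vert]
        if not mask.any():
            raise ValidationError(f"vertebra {vert} not present in slice")
        idx = np.argwhere(mask)
        if (
            idx[:, 0].min() == 0
            or idx[:, 1].min() == 0
            or idx[:, 0].max() == slc.labels.shape[0] - 1
            or idx[:, 1].max() == slc.labels.shape[1] - 1
        ):
            warnings.append(f"{vert} touches the image border")
        mm = idx * sp
        raw_ant = _extreme_corner(mm, +1.0)
        raw_post = _extreme_corner(mm, -1.0)
        a_lo, a_hi = sorted((int(round(raw_post[0] / sp[0])), int(round(raw_ant[0] / sp[0]))))
        tilt = _edge_tilt_deg(idx, sp, a_lo, a_hi)
        points[f"{vert}_ant"] = _extreme_corner(mm, +1.0, tilt)
        points[f"{vert}_post"] = _extreme_corner(mm, -1.0, tilt)
    return LandmarkSet(
        case_id=case_id, reader_id="detector", points=points, warnings=tuple(warnings)
    )


def pairwise_distance(a: LandmarkSet, b: LandmarkSet, name: str) -> float:
    """Euclidean distance in mm between two readers' versions of a landmark."""
    if name not in a.points or name not in b.points:
        raise ValidationError(f"landmark {name} absent")
    return float(np.linalg.norm(a.points[name] - b.points[name]))


def fit_fence(distances) -> float:
    """Tukey upper fence Tp = Q3 + 1.5 × (Q3 − Q1) of a distance sample.

    Quartiles use linear interpolation of order statistics (the common
    "type-7" definition).
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size < 4:
        raise ValidationError("insufficient data for quartiles (need >= 4 values)")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    q1, q3 = np.percentile(d, [25, 75], method="linear")
    return float(q3 + 1.5 * (q3 - q1))


def fit_fences(a_sets: list[LandmarkSet], b_sets: list[LandmarkSet]) -> OutlierFence:
    """Fit per-landmark fences from paired training annotations."""
    if len(a_sets) != len(b_sets):
        raise ValidationError("paired landmark lists differ in length")
    fences = {
        name: fit_fence([pairwise_distance(a, b, name) for a, b in zip(a_sets, b_sets)])
        for name in LANDMARK_NAMES
    }
    return OutlierFence(per_landmark_tp_mm=fences)


def classify_reliability(
    a: LandmarkSet, b: LandmarkSet, fence: OutlierFence
) -> dict[str, bool]:
    """Per-landmark reliability: reliable iff distance is strictly below Tp."""
    return {
        name: pairwise_distance(a, b, name) < fence.tp(name) for name in LANDMARK_NAMES
    }


def adjudicate(
    a: LandmarkSet, b: LandmarkSet, c: LandmarkSet, name: str
) -> tuple[np.ndarray, tuple[str, str]]:
    """Resolve an unreliable landmark with a third reader.

    Among the three reader pairs, the pair with the smallest distance for this
    landmark wins; the final point is the midpoint of that pair's two points.
    Distance ties break on the lexicographically smallest reader-id pair.
    """
    readers = {s.reader_id: s for s in (a, b, c)}
    if len(readers) != 3:
        raise ValidationError("adjudication needs three distinct reader ids")
    candidates = []
    for ra, rb in combinations(sorted(readers), 2):
        d = pairwise_distance(readers[ra], readers[rb], name)
        candidates.append((d, (ra, rb)))
    d, pair = min(candidates, key=lambda t: (t[0], t[1]))
    mid = 0.5 * (readers[pair[0]].points[name] + readers[pair[1]].points[name])
    return mid, pair


def reconcile_measurements(
    x, y, tcobb: float, third=None
) -> tuple[np.ndarray, list[int]]:
    """Reconcile paired Cobb readings into final reference angles.

    Cases whose absolute reader difference is strictly less than ``tcobb``
    get the two readings' mean; others are flagged for third-reader
    adjudication.  If ``third`` supplies the extra readings, the flagged
    cases take the mean of the smallest-difference reader pair (ties break in
    the order (x,y), (x,third), (y,third)); otherwise they are NaN.

    Returns (final angles, indices flagged as unreliable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired angle lists must have equal length")
    if third is not None:
        third = np.asarray(third, dtype=float)
        if third.shape != x.shape:
            raise ValidationError("third-reader list must match the paired lists")
    final = np.empty_like(x)
    flagged: list[int] = []
    for i in range(x.size):
        if abs(x[i] - y[i]) < tcobb:
            final[i] = 0.5 * (x[i] + y[i])
            continue
        flagged.append(i)
        if third is None:
            final[i] = np.nan
        else:
            pairs = [(x[i], y[i]), (x[i], third[i]), (y[i], third[i])]
            u, v = min(pairs, key=lambda p: abs(p[0] - p[1]))
            final[i] = 0.5 * (u + v)
    return final, flagged


def write_reconciliation_report(
    a_sets: list[LandmarkSet],
    b_sets: list[LandmarkSet],
    fence: OutlierFence,
    path: str | Path,
    third_sets: list[LandmarkSet] | None = None,
) -> Path:
    """Write a per-case, per-landmark reconciliation table as CSV.

    Columns: case, landmark, distance (mm), fence (mm), reliable flag and —
    where a third reader is available for unreliable points — the adjudicated
    point and winning reader pair.  Reliable points take the two readers'
    midpoint, mirroring the final-key-point rule.
    """
    if len(a_sets) != len(b_sets):
        raise ValidationError("paired landmark lists differ in length")
    rows = []
    third_by_case = {s.case_id: s for s in third_sets} if third_sets else {}
    for a, b in zip(a_sets, b_sets):
        if a.case_id != b.case_id:
            raise ValidationError(f"case mismatch: {a.case_id} vs {b.case_id}")
        for name in LANDMARK_NAMES:
            d = pairwise_distance(a, b, name)
            tp = fence.tp(name)
            reliable = d < tp
            if reliable:
                pt = 0.5 * (a.points[name] + b.points[name])
                pair = (a.reader_id, b.reader_id)
            elif a.case_id in third_by_case:
                pt, pair = adjudicate(a, b, third_by_case[a.case_id], name)
            else:
                pt, pair = (np.nan, np.nan), ("", "")
            rows.append(
                {
                    "case_id": a.case_id,
                    "landmark": name,
                    "distance_mm": d,
                    "fence_mm": tp,
                    "reliable": reliable,
                    "final_anterior_mm": pt[0],
                    "final_superior_mm": pt[1],
                    "chosen_pair": "|".join(pair),
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
    return path
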