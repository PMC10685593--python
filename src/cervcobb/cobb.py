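"""Sagittal Cobb-angle estimators.

The C2–C7 sagittal Cobb angle is the angle between the extension lines of the
C2 and C7 inferior vertebral endplates in the midsagittal plane.  Two
estimators are provided:

* **four-points**: each endplate line is the chord through its detected
  anterior and posterior corners (LC2, LC7);
* **line-fitting**: point sets PC2 and PC7 are sampled along each inferior
  edge of the segmentation mask between the corners, and a total-least-squares
  line (DC2, DC7) is fitted to each.

Sign convention: with anterior = +x and superior = +y, a line's inclination is
``atan2(superior, anterior)`` of its canonical direction, and the Cobb angle
is ``inclination(C2) − inclination(C7)`` wrapped to (−90°, 90°].  Lordosis
(C2 inferior endplate tilted superior-anteriorly relative to C7's) is
therefore positive.  Angles are invariant to in-plane translation, uniform
scaling and — because the least squares is orthogonal, not coordinate-wise —
rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion

from .volume_io import LandmarkSet, SagittalSlice, ValidationError

__all__ = [
    "DegenerateGeometryError",
    "EndplateLine",
    "EdgePointSet",
    "CobbMeasurement",
    "line_from_corners",
    "extract_edge_points",
    "fit_line_least_squares",
    "cobb_angle",
    "measure_four_points",
    "measure_line_fitting",
]

#: Tolerance (mm) within which supplied corners are snapped to the mask
#: boundary when extracting edge point sets.  Generous enough to tolerate
#: realistic reader/detector scatter (inter-reader fences are a few mm) while
#: still rejecting grossly misplaced corners.
CORNER_SNAP_TOL_MM = 6.0


class DegenerateGeometryError(ValidationError):
    """Coincident points, isotropic scatter or other degenerate geometry."""


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    """Unit direction with anterior component >= 0 (if 0, superior > 0)."""
    d = np.asarray(d, dtype=float)
    n = float(np.hypot(d[0], d[1]))
    if n == 0.0:
        raise DegenerateGeometryError("zero-length direction")
    d = d / n
    if d[0] < 0.0 or (d[0] == 0.0 and d[1] < 0.0):
        d = -d
    return d


@dataclass(frozen=True)
class EndplateLine:
    """A 2-D inferior-endplate line: point + canonical unit direction."""

    point_mm: np.ndarray
    direction: np.ndarray
    source: str  # "corner-segment" (LC2/LC7) or "least-squares-fit" (DC2/DC7)

    def __post_init__(self) -> None:
        object.__setattr__(self, "point_mm", np.asarray(self.point_mm, dtype=float))
        object.__setattr__(self, "direction", _canonical_direction(self.direction))

    @property
    def inclination_deg(self) -> float:
        """Signed inclination in (−90°, 90°] relative to the anterior axis."""
        return math.degrees(math.atan2(self.direction[1], self.direction[0]))


@dataclass(frozen=True)
class EdgePointSet:
    """Ordered inferior-edge points (posterior → anterior) for one vertebra."""

    vertebra: str  # "C2" or "C7"
    points_mm: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_mm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValidationError("edge point set needs >= 2 two-dimensional points")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValidationError("duplicate points in edge point set")
        object.__setattr__(self, "points_mm", pts)

    def __len__(self) -> int:
        return len(self.points_mm)


@dataclass(frozen=True)
class CobbMeasurement:
    """A signed Cobb angle in degrees, tagged with the method that produced it."""

    case_id: str
    method: str  # four_points | line_fitting | manual_reference
    angle_deg: float

    def __post_init__(self) -> None:
        if not (-90.0 < self.angle_deg <= 90.0):
            raise ValidationError(f"angle {self.angle_deg} outside (-90, 90]")


def line_from_corners(ant: np.ndarray, post: np.ndarray, source: str = "corner-segment") -> EndplateLine:
    """Endplate line through the anterior and posterior corners (LC2/LC7)."""
    ant = np.asarray(ant, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.allclose(ant, post, atol=0.0):
        raise DegenerateGeometryError("degenerate endplate segment: coincident corners")
    return EndplateLine(point_mm=post, direction=ant - post, source=source)


def _wrap_half_turn(deg: float) -> float:
    """Map an angle difference to (−90, 90] exactly (no modulo rounding)."""
    if deg > 90.0:
        deg -= 180.0
    elif deg <= -90.0:
        deg += 180.0
    return deg


def cobb_angle(c2: EndplateLine, c7: EndplateLine) -> float:
    """Signed Cobb angle: inclination(C2) − inclination(C7), in (−90°, 90°].

    Antisymmetric under argument swap; its magnitude is the acute angle
    between the two lines.
    """
    return _wrap_half_turn(c2.inclination_deg - c7.inclination_deg)


def measure_four_points(lm: LandmarkSet) -> CobbMeasurement:
    """Four-points Cobb estimate from the four endplate corners."""
    lc2 = line_from_corners(lm["C2_ant"], lm["C2_post"])
    lc7 = line_from_corners(lm["C7_ant"], lm["C7_post"])
    return CobbMeasurement(case_id=lm.case_id, method="four_points", angle_deg=cobb_angle(lc2, lc7))


def extract_edge_points(
    slc: SagittalSlice,
    vertebra: str,
    ant: np.ndarray,
    post: np.ndarray,
    snap_tol_mm: float = CORNER_SNAP_TOL_MM,
) -> EdgePointSet:
    """Sample the inferior-edge boundary points between two corners (PC2/PC7).

    The supplied corners are snapped to the nearest boundary pixel of the
    vertebra region (error if farther than ``snap_tol_mm``); every boundary
    pixel column between them contributes its most inferior pixel, in physical
    mm, ordered posterior → anterior.  Corner argument order does not matter.
    """
    if vertebra not in slc.label_map:
        raise ValidationError(f"vertebra {vertebra} not in label map")
    mask = slc.labels == slc.label_map[vertebra]
    if not mask.any():
        raise ValidationError(f"vertebra {vertebra} not present in slice")
    sp = np.asarray(slc.spacing_mm)
    boundary = mask & ~binary_erosion(mask, border_value=0)
    bidx = np.argwhere(boundary)
    bmm = bidx * sp

    cols = []
    for corner in (ant, post):
        corner = np.asarray(corner, dtype=float)
        d = np.linalg.norm(bmm - corner, axis=1)
        j = int(np.argmin(d))
        if d[j] > snap_tol_mm:
            raise ValidationError(
                f"corner {corner} is {d[j]:.2f} mm from the {vertebra} boundary "
                f"(tolerance {snap_tol_mm} mm)"
            )
        cols.append(int(bidx[j][0]))
    lo, hi = min(cols), max(cols)

    pts = []
    for ia in range(lo, hi + 1):
        rows = np.nonzero(mask[ia])[0]
        if rows.size == 0:
            continue
        pts.append((ia * sp[0], rows.min() * sp[1]))
    if len(pts) < 2:
        raise ValidationError(f"fewer than 2 inferior-edge points for {vertebra}")
    return EdgePointSet(vertebra=vertebra, points_mm=np.asarray(pts))


def fit_line_least_squares(pts: EdgePointSet) -> EndplateLine:
    """Total-least-squares line through an edge point set (DC2/DC7).

    The line passes through the centroid with direction along the principal
    axis of the points' scatter, i.e. it minimizes the summed squared
    *orthogonal* distances — which makes the fit equivariant under in-plane
    rotation, unlike a vertical-offset regression.
    """
    x = pts.points_mm
    centroid = x.mean(axis=0)
    centered = x - centroid
    if np.allclose(centered, 0.0):
        raise DegenerateGeometryError("all edge points identical")
    # Principal axis via SVD of the centred coordinates.
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[0] > 0 and (sv[0] - sv[1]) / sv[0] < 1e-9:
        raise DegenerateGeometryError("degenerate fit: isotropic point scatter")
    return EndplateLine(point_mm=centroid, direction=vt[0], source="least-squares-fit")


def measure_line_fitting(slc: SagittalSlice, lm: LandmarkSet) -> CobbMeasurement:
    """Line-fitting Cobb estimate: fit DC2/DC7 to the inferior edges.

    The landmark corners serve only as reference points delimiting the edge
    span; the angle comes from the fitted lines, which averages out both
    corner noise and endplate curvature.
    """
    dc2 = fit_line_least_squares(extract_edge_points(slc, "C2", lm["C2_ant"], lm["C2_post"]))
    dc7 = fit_line_least_squares(extract_edge_points(slc, "C7", lm["C7_ant"], lm["C7_post"]))
    return CobbMeasurement(case_id=lm.case_id, method="line_fitting", angle_deg=cobb_angle(dc2, dc7))
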