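"""Circle geometry of contractile-ring annotations.

A dividing cell and its constricting actomyosin ring are each annotated
with three points in the division-plane view; the circumcircle through
each triple gives the cell radius ``R`` and ring radius ``r``.  From the
two circles the per-frame metrics follow:

* ring closure  ``100 * (1 - r/R)``  — 0% at onset, 100% when the ring
  has fully constricted (the raw ratio ``r/R*100`` is kept alongside);
* furrow asymmetry  ``100 * D/R``  with ``D`` the distance between the
  cell and ring centers — 0% for concentric closure, 100% for fully
  unilateral closure;
* apical displacement — the signed projection of the ring-center offset
  onto the apical axis of the epithelium, positive when the furrow
  terminates apically.

Coordinates follow the image convention (origin top-left, y increasing
downward) and are in micrometers throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    CollinearPointsError,
    DuplicatePointError,
    GeometryError,
    NonUnitAxisError,
    RingLargerThanCellError,
)

__all__ = [
    "Point2D",
    "CircleFit",
    "AnnotatedFrame",
    "FrameMetrics",
    "circle_through_points",
    "closure_percent",
    "asymmetry_percent",
    "apical_displacement",
    "frame_metrics",
]

#: scale-free collinearity threshold: triangle area < TOL * (max pairwise dist)^2
COLLINEARITY_TOL = 1e-6

#: annotation-jitter tolerance on r/R near cytokinesis onset; ratios in
#: (1, 1 + RATIO_TOL] clamp closure to 0, larger ratios are an error
RATIO_TOL = 0.02


@dataclass(frozen=True)
class Point2D:
    """A point in the division-plane image, in µm."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class CircleFit:
    """A fitted circle: center, radius and RMS point-to-circle residual (µm).

    For exactly three non-collinear points the fit is the circumcircle and
    the residual is zero to numerical precision.
    """

    center: Point2D
    radius: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError(f"radius must be positive, got {self.radius}")
        if self.residual < 0:
            raise GeometryError("residual must be non-negative")


@dataclass(frozen=True)
class AnnotatedFrame:
    """One timepoint's annotation: three cell-outline points, three ring
    points, the timestamp (seconds since movie start) and the apical unit
    vector for this trace."""

    time: float
    cell_points: tuple[Point2D, Point2D, Point2D]
    ring_points: tuple[Point2D, Point2D, Point2D]
    apical_axis: Point2D = field(default=Point2D(0.0, 1.0))

    def __post_init__(self) -> None:
        norm = math.hypot(self.apical_axis.x, self.apical_axis.y)
        if abs(norm - 1.0) > 1e-6:
            raise NonUnitAxisError(f"|apical_axis| = {norm:.6g}, expected 1")


@dataclass(frozen=True)
class FrameMetrics:
    """Per-frame read-outs derived from the two fitted circles."""

    closure_pct: float
    asymmetry_pct: float
    apical_displacement: float
    cell: CircleFit
    ring: CircleFit

    @property
    def ring_fraction_pct(self) -> float:
        """Raw r/R*100 (the complement of closure), retained for reference."""
        return 100.0 * self.ring.radius / self.cell.radius


def _check_distinct(p1: Point2D, p2: Point2D, p3: Point2D) -> None:
    pts = [p1, p2, p3]
    for i in range(3):
        for j in range(i + 1, 3):
            if pts[i].x == pts[j].x and pts[i].y == pts[j].y:
                raise DuplicatePointError(
                    f"annotation points {i} and {j} coincide at "
                    f"({pts[i].x}, {pts[i].y})"
                )


def circle_through_points(p1: Point2D, p2: Point2D, p3: Point2D) -> CircleFit:
    """Circumcircle through three non-collinear points.

    Solves the algebraic form ``x^2 + y^2 + D x + E y + F = 0`` as a
    linear system, which is exact for three points.  Degeneracy is tested
    scale-free: the triangle area must exceed ``COLLINEARITY_TOL`` times
    the squared maximal pairwise distance.

    Raises
    ------
    DuplicatePointError
        if two points coincide.
    CollinearPointsError
        if the points are collinear within tolerance (a degenerate
        annotation, e.g. all three on a flat furrow edge).
    """
    _check_distinct(p1, p2, p3)
    pts = np.array([[p1.x, p1.y], [p2.x, p2.y], [p3.x, p3.y]], dtype=float)

    d01 = np.linalg.norm(pts[1] - pts[0])
    d02 = np.linalg.norm(pts[2] - pts[0])
    d12 = np.linalg.norm(pts[2] - pts[1])
    scale = max(d01, d02, d12)
    cross = (pts[1][0] - pts[0][0]) * (pts[2][1] - pts[0][1]) - (
        pts[1][1] - pts[0][1]
    ) * (pts[2][0] - pts[0][0])
    area = 0.5 * abs(cross)
    if area <= COLLINEARITY_TOL * scale**2:
        raise CollinearPointsError(
            f"annotation points are collinear (area {area:.3g} µm², "
            f"span {scale:.3g} µm)"
        )

    # x^2 + y^2 + D x + E y + F = 0  ->  [x y 1] [D E F]' = -(x^2 + y^2)
    a = np.column_stack([pts[:, 0], pts[:, 1], np.ones(3)])
    b = -(pts[:, 0] ** 2 + pts[:, 1] ** 2)
    coef_d, coef_e, coef_f = np.linalg.solve(a, b)
    cx, cy = -coef_d / 2.0, -coef_e / 2.0
    radius = math.sqrt(cx * cx + cy * cy - coef_f)

    dists = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    residual = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return CircleFit(center=Point2D(float(cx), float(cy)), radius=float(radius),
                     residual=residual)


def closure_percent(ring: CircleFit, cell: CircleFit) -> float:
    """Ring closure as a percentage, ``100 * (1 - r/R)``.

    0% for an unconstricted ring (r = R), 100% for a point ring.  Ratios
    slightly above 1 — annotation jitter near onset — clamp to 0% up to
    ``RATIO_TOL``; larger ratios raise :class:`RingLargerThanCellError`.
    """
    ratio = ring.radius / cell.radius
    if ratio > 1.0 + RATIO_TOL:
        raise RingLargerThanCellError(
            f"ring radius {ring.radius:.3g} µm exceeds cell radius "
            f"{cell.radius:.3g} µm beyond the {RATIO_TOL:.0%} tolerance"
        )
    return float(np.clip(100.0 * (1.0 - ratio), 0.0, 100.0))


def asymmetry_percent(ring: CircleFit, cell: CircleFit) -> float:
    """Furrow asymmetry, ``100 * D/R`` with D the center-to-center distance."""
    d = math.hypot(ring.center.x - cell.center.x, ring.center.y - cell.center.y)
    return 100.0 * d / cell.radius


def apical_displacement(
    ring: CircleFit, cell: CircleFit, apical_axis: Point2D
) -> float:
    """Signed ring-center displacement along the apical axis (µm).

    Positive values mean the ring center has moved toward the apical side
    of the epithelium, the direction in which furrows terminate.
    """
    norm = math.hypot(apical_axis.x, apical_axis.y)
    if abs(norm - 1.0) > 1e-6:
        raise NonUnitAxisError(f"|apical_axis| = {norm:.6g}, expected 1")
    dx = ring.center.x - cell.center.x
    dy = ring.center.y - cell.center.y
    return dx * apical_axis.x + dy * apical_axis.y


def frame_metrics(frame: AnnotatedFrame, index: int | None = None) -> FrameMetrics:
    """All per-frame metrics from one annotated frame.

    Fits both circles and composes closure, asymmetry and apical
    displacement; geometry errors are re-raised with the frame index (or
    timestamp) attached for traceability.
    """
    label = f"frame {index}" if index is not None else f"frame at t={frame.time}s"
    try:
        cell = circle_through_points(*frame.cell_points)
    except GeometryError as exc:
        raise type(exc)(f"{label}, cell outline: {exc}") from exc
    try:
        ring = circle_through_points(*frame.ring_points)
    except GeometryError as exc:
        raise type(exc)(f"{label}, contractile ring: {exc}") from exc
    try:
        closure = closure_percent(ring, cell)
    except GeometryError as exc:
        raise type(exc)(f"{label}: {exc}") from exc
    return FrameMetrics(
        closure_pct=closure,
        asymmetry_pct=asymmetry_percent(ring, cell),
        apical_displacement=apical_displacement(ring, cell, frame.apical_axis),
        cell=cell,
        ring=ring,
    )
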