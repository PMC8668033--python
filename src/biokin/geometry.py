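"""Calibration, registration and biokinemetric-triangle measurement.

The biokinemetric triangle is a per-segment surrogate for sagittal motion
geometry.  Its baseline lies on the lower vertebra's upper endplate and runs
from the anterior (leading) edge — landmark 1 — to the ascending facet —
landmark 2.  The apex — landmark 3 — sits at the posterior edge of the upper
vertebra at the roof of the neuroforamen.  Registering every frame of an exam
into the segment frame (baseline landmark 1 at the origin, landmark 2 on the
positive first axis) fixes the baseline, so segmental motion changes only the
triangle's height; the unsigned triangle area then tracks the apex excursion
and serves as the motion measure.

Coordinates are 2-D sagittal, in millimetres after calibration with a gauged
X-ray ball of known diameter.  After registration the first axis runs
posteriorly along the lower endplate and the second axis points cranially.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateBaselineError,
    DegenerateTriangleWarning,
    IncompleteFrameError,
    InvalidCalibrationError,
    InvalidDirectionError,
)

__all__ = [
    "LandmarkPoint",
    "CalibrationRecord",
    "BiokinemetricTriangle",
    "EndplatePair",
    "calibrate_scale",
    "triangle_area",
    "triangle_area_points",
    "register_to_segment_frame",
    "endplate_angle",
]

_POINT_IDS = (1, 2, 3)


@dataclass(frozen=True)
class LandmarkPoint:
    """A single annotated landmark of one segment in one frame.

    ``point_id`` 1 and 2 span the baseline on the lower endplate, 3 is the
    apex at the neuroforamen roof.  Units are pixels before calibration and
    millimetres after.
    """

    point_id: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.point_id not in _POINT_IDS:
            raise IncompleteFrameError(f"point_id must be 1, 2 or 3, got {self.point_id}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise IncompleteFrameError("landmark coordinates must be finite")


@dataclass(frozen=True)
class CalibrationRecord:
    """Scalar pixel-to-millimetre scale from a gauged X-ray ball."""

    ball_true_diameter_mm: float
    ball_image_diameter_px: float

    @property
    def scale(self) -> float:
        """Millimetres per pixel."""
        return self.ball_true_diameter_mm / self.ball_image_diameter_px

    def to_mm(self, px):
        return np.asarray(px, dtype=float) * self.scale

    def to_px(self, mm):
        return np.asarray(mm, dtype=float) / self.scale


def calibrate_scale(ball_true_diameter_mm: float, ball_image_diameter_px: float) -> CalibrationRecord:
    """Build a calibration record; both diameters must be finite and positive."""
    for name, value in (
        ("ball_true_diameter_mm", ball_true_diameter_mm),
        ("ball_image_diameter_px", ball_image_diameter_px),
    ):
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise InvalidCalibrationError(f"{name} must be finite and > 0, got {value!r}")
    return CalibrationRecord(float(ball_true_diameter_mm), float(ball_image_diameter_px))


def triangle_area_points(p1, p2, p3) -> float:
    """Unsigned triangle area by the shoelace formula, |cross(p2-p1, p3-p1)|/2."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    u = p2 - p1
    v = p3 - p1
    return 0.5 * abs(u[0] * v[1] - u[1] * v[0])


@dataclass(eq=False)
class BiokinemetricTriangle:
    """Three calibrated landmarks of one segment in the registered frame.

    The area is unsigned ("area content"); collinear landmarks yield zero
    area and set :attr:`degenerate` instead of raising.
    """

    level: str
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        self.p3 = np.asarray(self.p3, dtype=float)
        if np.allclose(self.p1, self.p2):
            raise DegenerateBaselineError(
                f"baseline landmarks coincide at level {self.level!r}"
            )
        if self.area == 0.0:
            self.degenerate = True

    @property
    def baseline_length(self) -> float:
        return float(np.hypot(*(self.p2 - self.p1)))

    @property
    def area(self) -> float:
        """Triangle area S in mm^2."""
        return triangle_area_points(self.p1, self.p2, self.p3)

    @property
    def height(self) -> float:
        """Apex height above the baseline: 2*S / baseline."""
        return 2.0 * self.area / self.baseline_length


def triangle_area(t: BiokinemetricTriangle) -> float:
    """Area of a triangle (mm^2); warns on collinear landmarks."""
    a = t.area
    if a == 0.0:
        warnings.warn(
            f"collinear landmarks at level {t.level!r}: zero area",
            DegenerateTriangleWarning,
            stacklevel=2,
        )
    return a


def _frame_to_array(frame) -> np.ndarray:
    """Normalize one frame's landmarks to a (3, 2) array ordered by point_id."""
    if isinstance(frame, Mapping):
        items = {int(k): (v.x, v.y) if isinstance(v, LandmarkPoint) else tuple(v) for k, v in frame.items()}
    else:
        seq = list(frame)
        if seq and isinstance(seq[0], LandmarkPoint):
            items = {p.point_id: (p.x, p.y) for p in seq}
        else:
            arr = np.asarray(seq, dtype=float)
            if arr.shape != (3, 2):
                raise IncompleteFrameError(f"expected 3 landmark points, got shape {arr.shape}")
            items = {i + 1: tuple(arr[i]) for i in range(3)}
    if set(items) != set(_POINT_IDS):
        raise IncompleteFrameError(f"frame must supply points 1, 2, 3; got {sorted(items)}")
    out = np.array([items[i] for i in _POINT_IDS], dtype=float)
    if not np.all(np.isfinite(out)):
        raise IncompleteFrameError("landmark coordinates must be finite")
    return out


def register_points(points_mm: np.ndarray) -> np.ndarray:
    """Rigidly register frames of (3, 2) mm landmarks into the segment frame.

    Each frame is translated so landmark 1 sits at the origin and rotated so
    landmark 2 lies on the positive first axis.  A rigid transform, so areas
    are unchanged.
    """
    P = np.asarray(points_mm, dtype=float)
    single = P.ndim == 2
    if single:
        P = P[None]
    u = P[:, 1] - P[:, 0]
    L = np.hypot(u[:, 0], u[:, 1])
    if np.any(L <= 0.0):
        raise DegenerateBaselineError("baseline landmarks coincide in at least one frame")
    c = u[:, 0] / L
    s = u[:, 1] / L
    rel = P - P[:, :1, :]
    x = rel[..., 0] * c[:, None] + rel[..., 1] * s[:, None]
    y = -rel[..., 0] * s[:, None] + rel[..., 1] * c[:, None]
    out = np.stack([x, y], axis=-1)
    return out[0] if single else out


def register_to_segment_frame(
    raw_points_per_frame: Sequence,
    calibration: CalibrationRecord,
    level: str = "",
) -> list[BiokinemetricTriangle]:
    """Calibrate and register an exam's frames; returns one triangle per frame.

    ``raw_points_per_frame`` holds, per frame, three :class:`LandmarkPoint`
    (or a ``point_id -> (x, y)`` mapping, or a (3, 2) array ordered 1..3) in
    pixel coordinates.  Calibration converts px to mm; the rigid registration
    fixes the baseline across frames.
    """
    if not isinstance(calibration, CalibrationRecord):
        raise InvalidCalibrationError("a CalibrationRecord is required")
    frames = [_frame_to_array(f) for f in raw_points_per_frame]
    if not frames:
        return []
    P = calibration.to_mm(np.stack(frames))
    R = register_points(P)
    return [BiokinemetricTriangle(level, q[0], q[1], q[2]) for q in R]


def endplate_angle(lower_plate_dir, upper_plate_dir) -> float:
    """Signed angle in degrees from the lower to the upper endplate direction.

    Zero when the plates are parallel; result in (-180, 180].
    """
    a = np.asarray(lower_plate_dir, dtype=float)
    b = np.asarray(upper_plate_dir, dtype=float)
    if np.hypot(*a) == 0.0 or np.hypot(*b) == 0.0:
        raise InvalidDirectionError("endplate direction vectors must be nonzero")
    ang = math.degrees(math.atan2(a[0] * b[1] - a[1] * b[0], a[0] * b[0] + a[1] * b[1]))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass(frozen=True)
class EndplatePair:
    """Directed lower and upper endplate lines of one segment."""

    lower_plate_dir: tuple[float, float]
    upper_plate_dir: tuple[float, float]

    @property
    def angle(self) -> float:
        """Segmental endplate angle in degrees, (-180, 180]."""
        return endplate_angle(self.lower_plate_dir, self.upper_plate_dir)
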