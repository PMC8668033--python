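"""Per-segment range-of-motion curves on the percentage-of-movement axis.

A motion curve plots a segment's triangle area S against the percentage of
the whole spine section's inclination-to-reclination sweep.  The percentage
is measured from the global section angle: the signed angle between the most
caudal endplate baseline and the most cranial available baseline, mapped so
the inclination endpoint is 0 % and the reclination endpoint 100 %.  Sparse
3-pose exams are densified with a shape-preserving monotone cubic (PCHIP)
interpolant, which passes through every knot and cannot overshoot the knot
range — triangle areas are physical quantities.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import levels as _levels
from .errors import (
    IncompleteCurveError,
    IncompleteFrameError,
    IncompleteLevelError,
    InsufficientFamilyError,
    InsufficientKnotsError,
    MissingPoseError,
    MissingUpperPlateError,
    OutOfRangeFractionWarning,
    SchemaError,
    ZeroArcError,
)
from .geometry import BiokinemetricTriangle, CalibrationRecord, endplate_angle, register_points

__all__ = [
    "MotionFrame",
    "MotionCurve",
    "MotionSurface",
    "frames_from_landmarks",
    "movement_fraction",
    "build_rom_curve",
    "interpolate_curve",
    "conventional_rom",
    "motion_surface",
]

PHASES = ("inclination", "neutral", "reclination", "intermediate")

SOURCE_MEASURED = "measured"
SOURCE_INTERPOLATED = "interpolated"
SOURCE_VIRTUAL = "virtual"


@dataclass
class MotionFrame:
    """One acquisition of the whole section.

    ``triangles`` hold the registered per-level triangles; ``plate_dirs``
    keep each level's baseline direction in the raw (calibrated, unregistered)
    image frame for the global and conventional angle computations.
    """

    frame_index: int
    phase: str
    global_angle_deg: float
    triangles: dict[str, BiokinemetricTriangle]
    plate_dirs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise SchemaError(f"unknown phase {self.phase!r}; expected one of {PHASES}")


@dataclass
class MotionCurve:
    """Triangle area versus percentage of movement for one segment."""

    level: str
    fraction: np.ndarray
    area: np.ndarray
    source: str = SOURCE_MEASURED

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.fraction.size != self.area.size:
            raise IncompleteCurveError("fraction and area must have equal length")
        if self.fraction.size and np.any(np.diff(self.fraction) <= 0):
            raise IncompleteCurveError("fraction values must be strictly increasing")
        if np.any(self.area < 0):
            raise IncompleteCurveError("triangle areas cannot be negative")
        if self.source not in (SOURCE_MEASURED, SOURCE_INTERPOLATED, SOURCE_VIRTUAL):
            raise SchemaError(f"unknown curve source {self.source!r}")

    def __len__(self) -> int:
        return int(self.fraction.size)

    @property
    def s_max(self) -> float:
        return float(np.max(self.area))

    @property
    def s_min(self) -> float:
        return float(np.min(self.area))

    @property
    def delta_s(self) -> float:
        """Range of the area over the motion, S_max - S_min."""
        return self.s_max - self.s_min


def frames_from_landmarks(
    table: pd.DataFrame,
    calibration: CalibrationRecord,
    section: str | None = None,
) -> list[MotionFrame]:
    """Turn a landmark table into registered motion frames.

    The table must carry one row per (frame, level, point) with columns
    ``frame_index, phase, level, point_id, x_px, y_px``.  Every level must be
    present with all three points in every frame.
    """
    required = {"frame_index", "phase", "level", "point_id", "x_px", "y_px"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"landmark table missing columns {sorted(missing)}")
    if table.empty:
        raise SchemaError("landmark table is empty")

    level_labels = _levels.ordered_levels(table["level"].unique(), section)
    frame_ids = np.sort(table["frame_index"].unique())
    n_frames = frame_ids.size
    frame_pos = {int(f): i for i, f in enumerate(frame_ids)}

    phases: dict[int, str] = {}
    for fid, grp in table.groupby("frame_index"):
        ph = grp["phase"].unique()
        if ph.size != 1:
            raise SchemaError(f"frame {fid} carries multiple phases {sorted(ph)}")
        phases[int(fid)] = str(ph[0])

    registered: dict[str, np.ndarray] = {}
    raw_dirs: dict[str, np.ndarray] = {}
    for lv in level_labels:
        sub = table[table["level"] == lv]
        if sub.shape[0] != 3 * n_frames:
            raise IncompleteLevelError(
                f"level {lv!r} has {sub.shape[0]} rows, expected {3 * n_frames}"
            )
        sub = sub.sort_values(["frame_index", "point_id"])
        pids = sub["point_id"].to_numpy().reshape(n_frames, 3)
        if not np.all(pids == np.array([1, 2, 3])):
            raise IncompleteFrameError(f"level {lv!r}: each frame needs points 1, 2, 3")
        P = calibration.to_mm(sub[["x_px", "y_px"]].to_numpy(dtype=float).reshape(n_frames, 3, 2))
        registered[lv] = register_points(P)
        raw_dirs[lv] = P[:, 1] - P[:, 0]

    caudal, cranial = level_labels[-1], level_labels[0]
    frames = []
    for fid in frame_ids:
        i = frame_pos[int(fid)]
        tris = {
            lv: BiokinemetricTriangle(lv, *registered[lv][i]) for lv in level_labels
        }
        dirs = {lv: raw_dirs[lv][i] for lv in level_labels}
        g = endplate_angle(dirs[caudal], dirs[cranial])
        frames.append(MotionFrame(int(fid), phases[int(fid)], g, tris, dirs))
    return frames


def _endpoint_indices(frames: Sequence[MotionFrame]) -> tuple[int, int]:
    inc = [i for i, f in enumerate(frames) if f.phase == "inclination"]
    rec = [i for i, f in enumerate(frames) if f.phase == "reclination"]
    if not inc or not rec:
        raise MissingPoseError("exam must contain inclination and reclination poses")
    return inc[0], rec[-1]


def movement_fraction(frames: Sequence[MotionFrame]) -> np.ndarray:
    """Percentage of the global sweep for every frame.

    ``100 * (theta - theta_inc) / (theta_rec - theta_inc)``; the inclination
    frame maps to 0, the reclination frame to 100.  Intermediate frames
    beyond the endpoint arc are clamped with a warning.
    """
    if len(frames) < 2:
        raise IncompleteCurveError("at least two frames are required")
    i_inc, i_rec = _endpoint_indices(frames)
    theta = np.array([f.global_angle_deg for f in frames], dtype=float)
    denom = theta[i_rec] - theta[i_inc]
    if abs(denom) < 1e-12:
        raise ZeroArcError("inclination and reclination global angles coincide")
    frac = 100.0 * (theta - theta[i_inc]) / denom
    if np.any(frac < -1e-9) or np.any(frac > 100.0 + 1e-9):
        warnings.warn(
            "intermediate frame outside the inclination-reclination arc; clamped",
            OutOfRangeFractionWarning,
            stacklevel=2,
        )
    return np.clip(frac, 0.0, 100.0)


def build_rom_curve(frames: Sequence[MotionFrame], level: str) -> MotionCurve:
    """Measured RoM curve for one level, sorted by fraction.

    Frames sharing a fraction (after clamping) have their areas averaged.
    """
    if len(frames) < 2:
        raise IncompleteCurveError("a motion curve needs at least two frames")
    for f in frames:
        if level not in f.triangles:
            raise IncompleteLevelError(f"level {level!r} missing in frame {f.frame_index}")
    frac = movement_fraction(frames)
    area = np.array([f.triangles[level].area for f in frames], dtype=float)
    uniq, inverse = np.unique(frac, return_inverse=True)
    mean_area = np.bincount(inverse, weights=area) / np.bincount(inverse)
    return MotionCurve(level, uniq, mean_area, source=SOURCE_MEASURED)


def interpolate_curve(sparse: MotionCurve, n_points: int = 101) -> MotionCurve:
    """Shape-preserving monotone cubic (PCHIP) densification of a sparse curve.

    The output grid is the union of ``n_points`` uniform fractions over the
    knot span and the knots themselves, so every knot value is reproduced
    exactly and no value overshoots the local knot range.
    """
    if len(sparse) < 3:
        raise InsufficientKnotsError(
            f"interpolation needs >= 3 knots (the 3-pose exam), got {len(sparse)}"
        )
    if n_points < 2:
        raise InsufficientKnotsError("n_points must be >= 2")
    interp = PchipInterpolator(sparse.fraction, sparse.area)
    grid = np.union1d(
        np.linspace(sparse.fraction[0], sparse.fraction[-1], n_points), sparse.fraction
    )
    return MotionCurve(sparse.level, grid, np.maximum(interp(grid), 0.0), source=SOURCE_INTERPOLATED)


def conventional_rom(
    frames: Sequence[MotionFrame],
    level: str,
    upper_plate_dirs: Mapping[int, np.ndarray] | None = None,
) -> float:
    """Conventional angle-based ROM: segment angle at reclination minus inclination.

    The segment angle is measured between the level's own baseline and the
    baseline of the segment above; for the topmost segment an explicit
    ``frame_index -> direction`` mapping for the upper plate must be given.
    """
    i_inc, i_rec = _endpoint_indices(frames)
    present = list(frames[0].triangles)
    if level not in present:
        raise IncompleteLevelError(f"level {level!r} not present in the exam")
    above = _levels.level_above(level, present)

    def seg_angle(frame: MotionFrame) -> float:
        lower = frame.plate_dirs[level]
        if above is not None:
            upper = frame.plate_dirs[above]
        elif upper_plate_dirs is not None and frame.frame_index in upper_plate_dirs:
            upper = upper_plate_dirs[frame.frame_index]
        else:
            raise MissingUpperPlateError(
                f"no upper endplate available for topmost level {level!r}"
            )
        return endplate_angle(lower, upper)

    return seg_angle(frames[i_rec]) - seg_angle(frames[i_inc])


@dataclass
class MotionSurface:
    """Relative segmental motion as a surface over (fraction, phase offset).

    ``curvature_max_location`` is the fraction at which the neutral-offset
    curve bends most strongly (largest |second derivative|); adjacent-segment
    motion initiation is expected near this locus.  Flat or linear curves
    have no such locus and set :attr:`indeterminate`.
    """

    level: str
    phase_offsets: np.ndarray
    fraction: np.ndarray
    grid: np.ndarray  # shape (n_offsets, n_fraction)
    curvature_max_location: float
    indeterminate: bool


def motion_surface(curve_family: Mapping[float, MotionCurve], level: str) -> MotionSurface:
    """Stack curves acquired at distinct phase offsets into a motion surface."""
    if len(curve_family) < 3:
        raise InsufficientFamilyError("a motion surface needs >= 3 curves at distinct offsets")
    offsets = np.array(sorted(curve_family), dtype=float)
    lo = max(curve_family[o].fraction[0] for o in offsets)
    hi = min(curve_family[o].fraction[-1] for o in offsets)
    grid_f = np.linspace(lo, hi, 101)
    rows = []
    for o in offsets:
        c = curve_family[o]
        if len(c) >= 3:
            rows.append(PchipInterpolator(c.fraction, c.area)(grid_f))
        else:
            rows.append(np.interp(grid_f, c.fraction, c.area))
    grid = np.vstack(rows)
    if not np.all(np.isfinite(grid)):
        raise InsufficientFamilyError("motion surface grid contains non-finite values")

    neutral = grid[int(np.argmin(np.abs(offsets)))]
    d2 = np.gradient(np.gradient(neutral, grid_f), grid_f)
    scale = max(1.0, float(np.max(np.abs(neutral))))
    if np.max(np.abs(d2)) <= 1e-10 * scale:
        return MotionSurface(level, offsets, grid_f, grid, float("nan"), True)
    loc = float(grid_f[int(np.argmax(np.abs(d2)))])
    return MotionSurface(level, offsets, grid_f, grid, loc, False)
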