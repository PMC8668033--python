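"""Virtual substitution, device-height recommendation and post-op prediction.

The planning chain mirrors the presurgical simulation workflow: substitute
the best segment's movement geometry into the worst segment, derive the disc
height the implant must restore (scaled by the section's level size ratios
and capped at the reference neutral height to prevent overcorrection), map it
onto the manufacturer's height grid, and predict how the immediately adjacent
segments redistribute the motion removed or added at the implanted level.

The redistribution model is this package's own surrogate for intersegmental
communication: the implanted level's area range is set to
``mobility_factor x healthy reference range`` and the difference to its
pre-op range is handed to the immediate neighbours in proportion to their
current ranges, conserving the section's total range.  ``dRoM`` — the
absolute change of a level's area range between two exams — is the
adjacent-segment effect measure and is correlated against outcome change
(relief is the negative outcome delta, preserving the sign convention that
larger adjacent dRoM goes with worse outcome).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import levels as _levels
from .errors import (
    ConfigError,
    DegenerateSubstitutionError,
    EmptyGridError,
    InsufficientCohortError,
    InvalidHeightError,
    LevelMismatchError,
    ReferenceGapError,
)
from .motion import SOURCE_VIRTUAL, MotionCurve
from .signature import ReferenceSurrogate

__all__ = [
    "DeviceSpec",
    "RoMChange",
    "OutcomeRecord",
    "HeightRecommendation",
    "PostopPrediction",
    "ImplantPlan",
    "CorrelationResult",
    "virtual_substitution",
    "optimal_device_height",
    "map_to_device_grid",
    "predict_postop_curves",
    "delta_rom",
    "correlate_delta_rom_outcome",
]

KIND_CAGE = "cage"
KIND_PROSTHESIS = "prosthesis"

# a device height matching the recommendation within this margin counts as exact
EXACT_HEIGHT_TOL_MM = 0.05

_SCORE_BOUNDS = {
    "NDI": (0.0, 1.0),
    "ODI": (0.0, 1.0),
    "NRS_neck": (0.0, 10.0),
    "NRS_arm": (0.0, 10.0),
    "COMI": (0.0, 10.0),
}


@dataclass(frozen=True)
class DeviceSpec:
    """A device reduced to its kind, mobility factor and height grid.

    ``mobility_factor`` is the fraction of the healthy segmental range the
    device preserves: 0 is a rigid fusion cage, 1 a perfectly physiological
    prosthesis.  Cages are forced to 0.
    """

    name: str
    kind: str
    mobility_factor: float
    available_heights: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in (KIND_CAGE, KIND_PROSTHESIS):
            raise ConfigError(f"device kind must be cage or prosthesis, got {self.kind!r}")
        if not 0.0 <= self.mobility_factor <= 1.0:
            raise ConfigError("mobility_factor must lie in [0, 1]")
        if self.kind == KIND_CAGE and self.mobility_factor != 0.0:
            object.__setattr__(self, "mobility_factor", 0.0)
        heights = tuple(float(h) for h in self.available_heights)
        if any(h <= 0 for h in heights):
            raise InvalidHeightError("device heights must be positive")
        if any(b <= a for a, b in zip(heights, heights[1:])):
            raise ConfigError("available_heights must be strictly increasing")
        object.__setattr__(self, "available_heights", heights)


@dataclass(frozen=True)
class RoMChange:
    """Absolute change of one level's area range between two exams."""

    level: str
    pre_range: float
    post_range: float

    @property
    def delta_rom(self) -> float:
        return abs(self.post_range - self.pre_range)


@dataclass(frozen=True)
class OutcomeRecord:
    """A patient-reported outcome score before and after treatment."""

    subject_id: str
    score_name: str
    pre: float
    post: float

    def __post_init__(self) -> None:
        if self.score_name not in _SCORE_BOUNDS:
            raise ConfigError(f"unknown score {self.score_name!r}")
        lo, hi = _SCORE_BOUNDS[self.score_name]
        for label, v in (("pre", self.pre), ("post", self.post)):
            if not lo <= v <= hi:
                raise ConfigError(
                    f"{self.score_name} {label}={v} outside nominal bounds [{lo}, {hi}]"
                )

    @property
    def delta(self) -> float:
        """Outcome change, post - pre (positive = worsening for disability scores)."""
        return self.post - self.pre


def virtual_substitution(
    patient: Mapping[str, MotionCurve],
    worst: str,
    best: str,
    reference: ReferenceSurrogate,
) -> MotionCurve:
    """Simulate the best segment's movement geometry into the worst segment.

    The best level's self-normalized curve is rescaled by the size-ratio
    quotient of the two levels, so the signature ratio transfers unchanged
    while the absolute scale respects that distal discs are larger.
    """
    if worst == best:
        raise DegenerateSubstitutionError("worst and best segment coincide")
    for lv in (worst, best):
        if lv not in patient:
            raise LevelMismatchError(f"level {lv!r} missing from the patient exam")
        if lv not in reference.size_ratios:
            raise ReferenceGapError(f"reference surrogate lacks level {lv!r}")
    quotient = reference.size_ratios[worst] / reference.size_ratios[best]
    donor = patient[best]
    return MotionCurve(worst, donor.fraction.copy(), donor.area * quotient, source=SOURCE_VIRTUAL)


@dataclass(frozen=True)
class HeightRecommendation:
    height_mm: float
    capped: bool
    no_change: bool
    current_height_mm: float


def optimal_device_height(
    heights: Mapping[str, float],
    worst: str,
    best: str,
    reference: ReferenceSurrogate,
) -> HeightRecommendation:
    """Disc height the implant should restore at the worst level.

    The best level's preserved height is carried over, scaled by the level
    size-ratio quotient, and capped at the reference neutral height of the
    worst level to prevent overcorrection.  If the result does not exceed the
    current worst-level height a no-change flag is set.
    """
    for lv in (worst, best):
        h = heights.get(lv)
        if h is None or not np.isfinite(h) or h <= 0:
            raise InvalidHeightError(f"invalid patient disc height for level {lv!r}: {h!r}")
    raw = heights[best] * reference.size_ratios[worst] / reference.size_ratios[best]
    cap = reference.neutral_heights[worst]
    capped = raw > cap
    h = min(raw, cap)
    return HeightRecommendation(h, capped, h <= heights[worst] + 1e-9, heights[worst])


def map_to_device_grid(h: float, device: DeviceSpec) -> tuple[float, bool]:
    """Nearest manufacturable height; ties break to the smaller (less distraction).

    Returns ``(grid_height, exact_available)`` with exactness meaning the grid
    height matches the recommendation within 0.05 mm.
    """
    grid = device.available_heights
    if not grid:
        raise EmptyGridError(f"device {device.name!r} has an empty height grid")
    diffs = np.abs(np.asarray(grid) - h)
    best = int(np.argmin(diffs))  # argmin takes the first (smaller) on ties
    return grid[best], bool(diffs[best] < EXACT_HEIGHT_TOL_MM)


@dataclass(frozen=True)
class PostopPrediction:
    """Virtual post-implantation curves and the redistribution bookkeeping."""

    curves: dict[str, MotionCurve]
    target_level: str
    removed_range: float
    neighbor_shares: dict[str, float]
    single_neighbor: bool


def _rescale_range(curve: MotionCurve, new_range: float, level: str) -> MotionCurve:
    """Rescale a curve's excursion below its own S_max to the given range."""
    old = curve.delta_s
    s_max = curve.s_max
    if old <= 1e-12:
        # flat curve gains range by opening a symmetric excursion below s_max
        shape = np.linspace(1.0, 0.0, len(curve)) if len(curve) > 1 else np.zeros(len(curve))
        area = s_max - shape * new_range
    else:
        area = s_max - (s_max - curve.area) * (new_range / old)
    return MotionCurve(level, curve.fraction.copy(), np.maximum(area, 0.0), source=SOURCE_VIRTUAL)


def predict_postop_curves(
    patient: Mapping[str, MotionCurve],
    target: str,
    device: DeviceSpec,
    reference: ReferenceSurrogate,
) -> PostopPrediction:
    """Virtual adjacent-level movement geometry after implanting *target*.

    The implanted level's range becomes ``mobility_factor x healthy reference
    range`` (reference ratio at patient scale); the removed range is handed to
    the immediate neighbours in proportion to their current ranges so the
    section total is conserved.  Non-adjacent levels are returned unchanged.
    A boundary target with a single neighbour is flagged, not rejected.
    """
    if target not in patient:
        raise LevelMismatchError(f"target level {target!r} missing from the patient exam")
    if target not in reference.curves:
        raise ReferenceGapError(f"reference surrogate lacks level {target!r}")
    present = list(patient)
    pre_curve = patient[target]

    ref = reference.curves[target]
    healthy_ratio = (ref.s_max - ref.s_min) / ref.s_max
    healthy_range = healthy_ratio * pre_curve.s_max
    post_target_range = device.mobility_factor * healthy_range
    removed = pre_curve.delta_s - post_target_range

    nbrs = _levels.neighbors(target, present)
    shares: dict[str, float] = {}
    if nbrs:
        ranges = np.array([patient[n].delta_s for n in nbrs], dtype=float)
        total = float(ranges.sum())
        weights = ranges / total if total > 0 else np.full(len(nbrs), 1.0 / len(nbrs))
        shares = dict(zip(nbrs, weights.tolist()))

    curves: dict[str, MotionCurve] = dict(patient)
    if abs(removed) > 1e-15 or pre_curve.source != SOURCE_VIRTUAL:
        curves[target] = _rescale_range(pre_curve, post_target_range, target)
    for n, w in shares.items():
        new_range = max(patient[n].delta_s + removed * w, 0.0)
        curves[n] = _rescale_range(patient[n], new_range, n)
    return PostopPrediction(curves, target, removed, shares, len(nbrs) == 1)


def delta_rom(pre: MotionCurve, post: MotionCurve) -> RoMChange:
    """|change of area range| of one level between two exams."""
    if pre.level != post.level:
        raise LevelMismatchError(f"levels differ: {pre.level!r} vs {post.level!r}")
    return RoMChange(pre.level, pre.delta_s, post.delta_s)


@dataclass(frozen=True)
class ImplantPlan:
    """Full recommendation for one patient."""

    target_level: str
    best_level: str
    recommended_height: float
    grid_height: float
    exact_available: bool
    capped: bool
    device: DeviceSpec
    virtual_substitution_curve: MotionCurve
    virtual_curves: dict[str, MotionCurve]
    delta_rom_per_level: tuple[RoMChange, ...]

    @property
    def adjacent_delta_rom(self) -> dict[str, float]:
        present = [c.level for c in self.delta_rom_per_level]
        adj = _levels.neighbors(self.target_level, present)
        return {c.level: c.delta_rom for c in self.delta_rom_per_level if c.level in adj}


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    undefined: bool


def correlate_delta_rom_outcome(
    delta_roms: Mapping[str, float],
    outcomes: Mapping[str, float] | Sequence[OutcomeRecord],
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> CorrelationResult:
    """Pearson correlation of mean adjacent dRoM with outcome relief.

    ``outcomes`` map subjects to outcome deltas (post - pre) or are outcome
    records; relief is the negated delta, so a deleterious association shows
    as a negative correlation.  Significance comes from a two-sided seeded
    permutation test.
    """
    if not isinstance(outcomes, Mapping):
        outcomes = {o.subject_id: o.delta for o in outcomes}
    subjects = sorted(set(delta_roms) & set(outcomes))
    if len(subjects) < 3:
        raise InsufficientCohortError("correlation needs >= 3 paired subjects")
    x = np.array([delta_roms[s] for s in subjects], dtype=float)
    relief = -np.array([outcomes[s] for s in subjects], dtype=float)
    if np.std(x) == 0.0 or np.std(relief) == 0.0:
        return CorrelationResult(float("nan"), float("nan"), len(subjects), True)
    xc = x - x.mean()
    yc = relief - relief.mean()
    nx = float(np.linalg.norm(xc))
    ny = float(np.linalg.norm(yc))
    r = float(xc @ yc / (nx * ny))
    rng = np.random.default_rng(rng)
    perms = np.empty(n_permutations)
    for i in range(n_permutations):
        perms[i] = xc @ rng.permutation(yc)
    perms /= nx * ny
    p = (1.0 + np.count_nonzero(np.abs(perms) >= abs(r) - 1e-15)) / (n_permutations + 1.0)
    return CorrelationResult(r, float(p), len(subjects), False)
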