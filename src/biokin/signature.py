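"""Segment signatures, spine number series and reproducibility analysis.

Each segment is condensed to a single dimensionless number, the ratio
``dS / S_max`` of its motion curve (range of the triangle area over the sweep
divided by the maximal area).  A spine section is then a short ordered series
of such numbers — its motion signature.  Repeating the functional exam twice
per subject lets the signature's reproducibility be quantified as the Bayes
error rate of a subject-identification problem: per-subject Gaussian
class-conditional densities with a shared diagonal covariance estimated from
within-subject session differences, evaluated by seeded Monte-Carlo
integration of the Bayes decision rule.  A leave-one-out nearest-neighbour
error is reported alongside as a distribution-free check.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator, UnivariateSpline

from . import levels as _levels
from .errors import (
    ConfigError,
    DuplicateLevelError,
    EmptyCurveError,
    IncompatibleSignatureError,
    IncompleteSectionError,
    InsufficientCohortError,
    NoCandidateError,
    ReferenceGapError,
)
from .motion import MotionCurve

__all__ = [
    "SegmentSignature",
    "SpineSignature",
    "ReferenceSurrogate",
    "ReproducibilityReport",
    "WorstSegmentResult",
    "BestSegmentResult",
    "segment_signature",
    "spine_signature",
    "signature_distance",
    "gaussian_bayes_error",
    "bayes_error_rate",
    "deviation_scores",
    "detect_worst_segment",
    "detect_best_segment",
    "estimate_disc_height",
]


@dataclass(frozen=True)
class SegmentSignature:
    """One segment's motion number: dS = S_max - S_min and the ratio dS/S_max."""

    level: str
    delta_s: float
    s_max: float
    ratio: float
    zero_motion: bool = False


def segment_signature(curve: MotionCurve) -> SegmentSignature:
    """Condense a motion curve to its dS/S_max signature.

    A curve whose maximal area is zero carries no motion information; its
    ratio is defined as 0 with ``zero_motion`` set.
    """
    if len(curve) == 0:
        raise EmptyCurveError(f"empty curve at level {curve.level!r}")
    s_max, s_min = curve.s_max, curve.s_min
    delta = s_max - s_min
    if s_max <= 0.0:
        return SegmentSignature(curve.level, delta, s_max, 0.0, zero_motion=True)
    return SegmentSignature(curve.level, delta, s_max, delta / s_max)


@dataclass(frozen=True)
class SpineSignature:
    """Ordered (cranial to caudal) series of segment signatures for a section."""

    section: str
    signatures: tuple[SegmentSignature, ...]

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(s.level for s in self.signatures)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([s.ratio for s in self.signatures], dtype=float)


def spine_signature(
    curves: Mapping[str, MotionCurve] | Iterable[MotionCurve], section: str
) -> SpineSignature:
    """Build the full-section number series; every section level must be present."""
    if isinstance(curves, Mapping):
        curve_list = list(curves.values())
    else:
        curve_list = list(curves)
    seen: dict[str, MotionCurve] = {}
    for c in curve_list:
        if c.level in seen:
            raise DuplicateLevelError(f"level {c.level!r} appears more than once")
        seen[c.level] = c
    expected = _levels.section_levels(section)
    missing = set(expected) - set(seen)
    if missing:
        raise IncompleteSectionError(f"missing levels {sorted(missing)} for {section} section")
    return SpineSignature(section, tuple(segment_signature(seen[lv]) for lv in expected))


def signature_distance(a: SpineSignature, b: SpineSignature) -> float:
    """Euclidean distance between two ratio series; 0 iff identical."""
    if a.section != b.section or a.levels != b.levels:
        raise IncompatibleSignatureError("signatures cover different sections or levels")
    return float(np.linalg.norm(a.ratios - b.ratios))


@dataclass(frozen=True)
class ReferenceSurrogate:
    """Stored healthy movement geometry per level of a section.

    ``curves`` are normalized motion curves (S_max = 1) on the [0, 100]
    fraction axis; ``neutral_heights`` are healthy neutral disc heights in mm;
    ``size_ratios`` encode that distal discs are larger than proximal ones and
    must be nondecreasing cranial to caudal.
    """

    section: str
    curves: Mapping[str, MotionCurve]
    neutral_heights: Mapping[str, float]
    size_ratios: Mapping[str, float]

    def __post_init__(self) -> None:
        order = _levels.section_levels(self.section)
        for name, mapping in (
            ("curves", self.curves),
            ("neutral_heights", self.neutral_heights),
            ("size_ratios", self.size_ratios),
        ):
            missing = set(order) - set(mapping)
            if missing:
                raise ConfigError(f"reference {name} missing levels {sorted(missing)}")
        ratios = [self.size_ratios[lv] for lv in order]
        if np.any(np.diff(ratios) < -1e-12):
            raise ConfigError("size ratios must be nondecreasing cranial to caudal")
        for lv in order:
            f = self.curves[lv].fraction
            if f[0] < -1e-9 or f[-1] > 100.0 + 1e-9:
                raise ConfigError(f"reference curve at {lv!r} leaves the [0, 100] axis")

    @property
    def levels(self) -> tuple[str, ...]:
        return _levels.section_levels(self.section)


# ---------------------------------------------------------------------------
# Reproducibility: Bayes error of subject identification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReproducibilityReport:
    """Fingerprint-style reproducibility of repeated signature measurements."""

    bayes_error: float
    mc_se: float
    nn_error: float
    n_subjects: int
    n_sessions: int
    ridged: bool


def gaussian_bayes_error(
    means: np.ndarray,
    variances: np.ndarray,
    n_draws: int = 100_000,
    rng: np.random.Generator | int | None = None,
    chunk: int = 20_000,
) -> tuple[float, float]:
    """Monte-Carlo Bayes error for equiprobable Gaussian classes.

    ``means`` has shape (k, d); ``variances`` is the shared diagonal
    covariance, shape (d,).  Returns the error estimate and its Monte-Carlo
    standard error.
    """
    rng = np.random.default_rng(rng)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    var = np.asarray(variances, dtype=float)
    if np.any(var <= 0):
        raise ConfigError("variances must be positive")
    k, d = means.shape
    if k < 2:
        raise InsufficientCohortError("at least two classes are required")
    sd = np.sqrt(var)
    errors = 0
    for start in range(0, n_draws, chunk):
        m = min(chunk, n_draws - start)
        labels = rng.integers(k, size=m)
        z = means[labels] + rng.standard_normal((m, d)) * sd
        d2 = (((z[:, None, :] - means[None, :, :]) ** 2) / var).sum(axis=-1)
        errors += int(np.count_nonzero(np.argmin(d2, axis=1) != labels))
    p = errors / n_draws
    return p, float(np.sqrt(max(p * (1 - p), 1e-12) / n_draws))


def bayes_error_rate(
    repeated: Mapping[str, tuple[SpineSignature, SpineSignature]],
    n_draws: int = 100_000,
    rng: np.random.Generator | int | None = None,
    ridge: float = 1e-12,
) -> ReproducibilityReport:
    """Reproducibility of twice-measured spine signatures across a cohort.

    Each subject is one class; the class mean is the subject's mean ratio
    vector and the shared diagonal covariance comes from within-subject
    session differences (Var = E[(x1 - x2)^2] / 2 per dimension).  Zero
    within-subject variance (identical duplicate sessions) is regularized
    with a small ridge and flagged.  A low Bayes error means repeated exams
    can be assigned to individuals like a fingerprint.
    """
    if len(repeated) < 2:
        raise InsufficientCohortError("reproducibility analysis needs >= 2 subjects")
    subjects = sorted(repeated)
    first = repeated[subjects[0]][0]
    X = []
    for sid in subjects:
        pair = repeated[sid]
        if len(pair) != 2:
            raise InsufficientCohortError(f"subject {sid!r} must have exactly 2 sessions")
        for sig in pair:
            if sig.section != first.section or sig.levels != first.levels:
                raise IncompatibleSignatureError("cohort signatures must share section and levels")
        X.append([pair[0].ratios, pair[1].ratios])
    X = np.asarray(X, dtype=float)  # (n, 2, d)

    means = X.mean(axis=1)
    diffs = X[:, 0, :] - X[:, 1, :]
    var = (diffs**2).mean(axis=0) / 2.0
    floor = ridge * max(1.0, float(var.max(initial=0.0)))
    ridged = bool(np.any(var < floor))
    var = np.maximum(var, floor)

    bayes, se = gaussian_bayes_error(means, var, n_draws=n_draws, rng=rng)

    flat = X.reshape(-1, X.shape[-1])
    labels = np.repeat(np.arange(len(subjects)), 2)
    d2 = ((flat[:, None, :] - flat[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = labels[np.argmin(d2, axis=1)]
    nn_error = float(np.mean(nn != labels))

    return ReproducibilityReport(bayes, se, nn_error, len(subjects), 2, ridged)


# ---------------------------------------------------------------------------
# Worst / best segment detection against the reference surrogate
# ---------------------------------------------------------------------------


def _curve_values_on_grid(curve: MotionCurve, grid: np.ndarray) -> np.ndarray:
    """Resample a curve onto the grid.

    Dense curves (>= 10 knots, e.g. videofluoroscopic sweeps) are regularized
    with a smoothing spline whose smoothing parameter comes from the
    second-difference noise estimate of the knot values, so a noise-free
    curve passes through its knots unchanged while annotation jitter is
    suppressed.  Sparse curves use the shape-preserving PCHIP interpolant.
    The motion curves themselves are never altered — regularization lives
    only inside comparison estimators.
    """
    clipped = np.clip(grid, curve.fraction[0], curve.fraction[-1])
    if len(curve) >= 10:
        a = curve.area
        d2 = a[:-2] - 2.0 * a[1:-1] + a[2:]
        noise_var = float(np.mean(d2**2) / 6.0)
        try:
            with warnings.catch_warnings():
                # fitpack warns when it cannot hit the smoothing target exactly;
                # the returned approximation is still the regularized fit we want
                warnings.simplefilter("ignore", UserWarning)
                spline = UnivariateSpline(curve.fraction, a, k=3, s=len(a) * noise_var)
            return spline(clipped)
        except Exception:  # singular fit on pathological knots: fall through
            pass
    if len(curve) >= 3:
        return PchipInterpolator(curve.fraction, curve.area)(clipped)
    return np.interp(grid, curve.fraction, curve.area)


def _normalized_on_grid(curve: MotionCurve, grid: np.ndarray) -> np.ndarray:
    """Resample a curve to the grid and self-normalize by its own maximum."""
    vals = _curve_values_on_grid(curve, grid)
    top = float(np.max(vals))
    if top <= 0.0:
        return np.zeros_like(vals)
    return vals / top


def deviation_scores(
    patient: Mapping[str, MotionCurve],
    reference: ReferenceSurrogate,
    grid_points: int = 101,
) -> dict[str, float]:
    """RMS difference between self-normalized patient and reference curves.

    Self-normalization by each curve's own S_max removes patient size
    effects, so the score is invariant to uniform area rescaling.
    """
    grid = np.linspace(0.0, 100.0, grid_points)
    scores: dict[str, float] = {}
    for lv, curve in patient.items():
        if lv not in reference.curves:
            raise ReferenceGapError(f"reference surrogate lacks level {lv!r}")
        p = _normalized_on_grid(curve, grid)
        r = _normalized_on_grid(reference.curves[lv], grid)
        scores[lv] = float(np.sqrt(np.mean((p - r) ** 2)))
    return scores


@dataclass(frozen=True)
class WorstSegmentResult:
    level: str
    deviations: dict[str, float]
    tie: bool


def detect_worst_segment(
    patient: Mapping[str, MotionCurve],
    reference: ReferenceSurrogate,
    grid_points: int = 101,
    tie_tol: float = 1e-9,
) -> WorstSegmentResult:
    """Level whose movement geometry deviates most from the reference.

    Near-equal maxima are flagged as a tie and broken toward the most caudal
    level (degeneration prevalence is caudal in both sections).
    """
    scores = deviation_scores(patient, reference, grid_points)
    ordered = _levels.ordered_levels(scores)
    top = max(scores.values())
    tied = [lv for lv in ordered if top - scores[lv] <= tie_tol]
    return WorstSegmentResult(tied[-1], scores, len(tied) > 1)


@dataclass(frozen=True)
class BestSegmentResult:
    level: str
    scores: dict[str, float]


def detect_best_segment(
    patient: Mapping[str, MotionCurve],
    heights: Mapping[str, float],
    reference: ReferenceSurrogate,
    weights: tuple[float, float] = (0.5, 0.5),
    exclude: Iterable[str] = (),
    grid_points: int = 101,
) -> BestSegmentResult:
    """Donor segment: preserved intersegmental height and near-reference geometry.

    ``score = w_h * (patient height / reference height) - w_c * deviation``;
    the level with the highest score among non-excluded levels wins.
    """
    w_h, w_c = weights
    if w_h < 0 or w_c < 0 or abs(w_h + w_c - 1.0) > 1e-9:
        raise ConfigError("weights must be nonnegative and sum to 1")
    deviations = deviation_scores(patient, reference, grid_points)
    candidates = [lv for lv in _levels.ordered_levels(deviations) if lv not in set(exclude)]
    if not candidates:
        raise NoCandidateError("all levels excluded from the best-segment search")
    scores: dict[str, float] = {}
    for lv in candidates:
        if lv not in heights:
            raise ReferenceGapError(f"no patient disc height for level {lv!r}")
        scores[lv] = w_h * (heights[lv] / reference.neutral_heights[lv]) - w_c * deviations[lv]
    best = max(candidates, key=lambda lv: scores[lv])
    return BestSegmentResult(best, scores)


def estimate_disc_height(
    curve: MotionCurve,
    baseline_length: float,
    reference_curve: MotionCurve | None = None,
) -> float:
    """Neutral disc height (mm) from a level's motion curve.

    With the baseline fixed, the triangle height is ``2 S / baseline`` and its
    minimum over the sweep is the apex's resting clearance — the disc-height
    proxy.  When the reference shape is available the areas are regressed on
    the reference's normalized motion profile, ``S ~ c0 + c1 * sigma``, and
    the intercept (motion-free area) gives ``h = 2 c0 / baseline``.

    The regression pairs the curve's samples with the reference profile by
    sweep rank (both the exam frames and the stored reference sample the
    sweep uniformly), not by the measured percentage-of-movement axis: the
    axis is normalized by the two noisy endpoint angles, which injects a
    shared scale error that would dominate the intercept.  The rank pairing
    makes the estimate insensitive to that and far more precise than the raw
    minimum under annotation noise.
    """
    if len(curve) == 0:
        raise EmptyCurveError(f"empty curve at level {curve.level!r}")
    if baseline_length <= 0:
        raise ConfigError("baseline length must be positive")
    if reference_curve is not None and len(curve) >= 3:
        ref_a = reference_curve.area
        lo, hi = float(np.min(ref_a)), float(np.max(ref_a))
        if hi - lo > 0:
            n = len(curve)
            sigma_ref = (ref_a - lo) / (hi - lo)
            rank = np.linspace(0.0, 1.0, n)
            sigma = np.interp(rank, np.linspace(0.0, 1.0, ref_a.size), sigma_ref)
            design = np.column_stack([np.ones_like(sigma), sigma])
            coef, *_ = np.linalg.lstsq(design, curve.area, rcond=None)
            h = 2.0 * float(coef[0]) / baseline_length
            if h > 0:
                return h
    return 2.0 * curve.s_min / baseline_length
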