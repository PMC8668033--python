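"""Seeded synthetic spines: calibrated landmark trajectories with known truth.

The generator emulates sagittal functional exams of a cervical (C2-C7) or
lumbar (L1-S1) section across an inclination -> neutral -> reclination sweep.
All segments share one motion characteristic — a logistic progression over
the sweep — but each sits at its own point of its movement sequence (a
per-level phase offset).  Two couplings are deliberately separated:

* angular kinematics: each segment contributes a fixed share of the global
  arc, so the per-level arc contributions always sum to the configured arc;
* area kinematics: each segment's triangle apex rides at
  ``disc height + mobility x amplitude x sigma(t)`` above its baseline, so
  degeneration (disc-height loss, hypo-/hypermobility) and device effects
  act on the measured area surrogate without breaking the angular sweep.

Landmark noise is isotropic Gaussian on pixel coordinates, calibrated per
level so the induced standard deviation of the triangle area is
``noise_sd_fraction x S_max`` — noise enters upstream, as in real annotation.
Every output is reproducible from the seed.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import levels as _levels
from .errors import ConfigError
from .geometry import CalibrationRecord, calibrate_scale
from .motion import SOURCE_MEASURED, MotionCurve
from .planning import DeviceSpec, OutcomeRecord
from .signature import ReferenceSurrogate

__all__ = [
    "Degeneration",
    "ImplantedDevice",
    "OutcomeModel",
    "SyntheticSpineConfig",
    "SpineTruth",
    "SyntheticCohort",
    "generate_reference_surrogate",
    "generate_exam",
    "exam_truth",
    "generate_identification_cohort",
    "generate_cohort",
]

LANDMARK_COLUMNS = (
    "subject_id",
    "session_id",
    "frame_index",
    "phase",
    "level",
    "point_id",
    "x_px",
    "y_px",
)

_SECTION_DEFAULTS = {
    "cervical": dict(
        global_arc_deg=60.0,
        level_weights=(0.19, 0.21, 0.22, 0.20, 0.18),
        height_base_mm=5.5,
        size_ratios=(1.00, 1.03, 1.06, 1.09, 1.12),
        phase_offsets=(-10.0, -5.0, 0.0, 5.0, 10.0),
        baseline_base_mm=15.0,
    ),
    "lumbar": dict(
        global_arc_deg=50.0,
        level_weights=(0.18, 0.20, 0.22, 0.21, 0.19),
        height_base_mm=10.0,
        size_ratios=(1.00, 1.05, 1.10, 1.15, 1.20),
        phase_offsets=(-10.0, -5.0, 0.0, 5.0, 10.0),
        baseline_base_mm=35.0,
    ),
}

# fraction of the posterior baseline at which the apex sits, and the vertebral
# body height used only to stack the chain (it never enters a measurement)
_APEX_X_FRACTION = 0.93
_BODY_HEIGHT_FACTOR = 0.8


@dataclass(frozen=True)
class Degeneration:
    """Segmental degeneration: disc-height loss and hypo-/hypermobility."""

    level: str
    height_loss_mm: float = 0.0
    mobility_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.height_loss_mm < 0:
            raise ConfigError("height_loss_mm must be >= 0")
        if not 0.0 <= self.mobility_scale <= 2.0:
            raise ConfigError("mobility_scale must lie in [0, 2]")


@dataclass(frozen=True)
class ImplantedDevice:
    """A device applied at one level; height defaults to the healthy height."""

    level: str
    device: DeviceSpec
    implanted_height_mm: float | None = None


@dataclass(frozen=True)
class OutcomeModel:
    """Outcome worsening = slope x mean adjacent dRoM + Gaussian noise.

    Scores are generated on the NDI fraction scale with plausible magnitudes
    (pre around 0.38); they are fixture values, not clinical predictions.
    """

    slope: float = 0.003
    noise_sd: float = 0.01
    score_name: str = "NDI"
    baseline_pre: float = 0.38

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ConfigError("outcome slope must be finite")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ConfigError("outcome noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticSpineConfig:
    """Study conditions for one synthetic spine.

    Defaults describe a realistic healthy section: disc heights and baseline
    lengths grow caudally with the level size ratios, segments share the
    logistic motion characteristic shifted by per-level phase offsets, and
    annotation noise defaults to 5 % of each level's maximal triangle area.
    """

    section: str = "cervical"
    global_arc_deg: float | None = None
    level_weights: tuple[float, ...] | None = None
    neutral_disc_heights: tuple[float, ...] | None = None
    size_ratios: tuple[float, ...] | None = None
    phase_offsets: tuple[float, ...] | None = None
    amplitude_fraction: float = 0.8
    steepness: float = 0.08
    baseline_base_mm: float | None = None
    noise_sd_fraction: float = 0.05
    degeneration: tuple[Degeneration, ...] = ()
    device: ImplantedDevice | None = None
    n_frames: int = 3
    seed: int = 0
    ball_true_diameter_mm: float = 30.0
    ball_image_diameter_px: float = 150.0

    def __post_init__(self) -> None:
        defaults = _SECTION_DEFAULTS.get(self.section)
        if defaults is None:
            raise ConfigError(f"unknown section {self.section!r}")
        n = len(_levels.section_levels(self.section))

        def fill(name, value):
            if value is None:
                value = defaults[name]
            object.__setattr__(self, name, value)
            return value

        arc = fill("global_arc_deg", self.global_arc_deg)
        weights = tuple(fill("level_weights", self.level_weights))
        ratios = tuple(fill("size_ratios", self.size_ratios))
        offsets = tuple(fill("phase_offsets", self.phase_offsets))
        fill("baseline_base_mm", self.baseline_base_mm)
        if self.neutral_disc_heights is None:
            heights = tuple(defaults["height_base_mm"] * r for r in ratios)
            object.__setattr__(self, "neutral_disc_heights", heights)
        heights = tuple(self.neutral_disc_heights)
        object.__setattr__(self, "neutral_disc_heights", heights)
        object.__setattr__(self, "level_weights", weights)
        object.__setattr__(self, "size_ratios", ratios)
        object.__setattr__(self, "phase_offsets", offsets)

        for name, seq in (
            ("level_weights", weights),
            ("neutral_disc_heights", heights),
            ("size_ratios", ratios),
            ("phase_offsets", offsets),
        ):
            if len(seq) != n:
                raise ConfigError(f"{name} must have {n} entries for {self.section}")
        if abs(sum(weights) - 1.0) > 1e-12 or any(w <= 0 for w in weights):
            raise ConfigError("level_weights must be positive and sum to 1")
        if any(h <= 0 for h in heights):
            raise ConfigError("neutral_disc_heights must be positive")
        if np.any(np.diff(ratios) < -1e-12):
            raise ConfigError("size_ratios must be nondecreasing cranial to caudal")
        if any(abs(o) > 20.0 for o in offsets):
            raise ConfigError("phase_offsets must lie in [-20, 20]")
        if arc <= 0 or self.amplitude_fraction <= 0 or self.steepness <= 0:
            raise ConfigError("global arc, amplitude fraction and steepness must be > 0")
        if self.noise_sd_fraction < 0:
            raise ConfigError("noise_sd_fraction must be >= 0")
        if self.n_frames < 3:
            raise ConfigError("n_frames must be >= 3 (inclination, neutral, reclination)")
        valid = set(self.levels)
        for deg in self.degeneration:
            if deg.level not in valid:
                raise ConfigError(f"degeneration at unknown level {deg.level!r}")
        if self.device is not None and self.device.level not in valid:
            raise ConfigError(f"device at unknown level {self.device.level!r}")

    @property
    def levels(self) -> tuple[str, ...]:
        return _levels.section_levels(self.section)

    @property
    def calibration(self) -> CalibrationRecord:
        return calibrate_scale(self.ball_true_diameter_mm, self.ball_image_diameter_px)


def _sigma_profiles(config: SyntheticSpineConfig, t: np.ndarray) -> np.ndarray:
    """Shared logistic motion characteristic per level, normalized to [0, 1].

    ``sigma_l(0) = 0`` and ``sigma_l(100) = 1`` exactly, so the sampled sweep
    always covers each segment's full configured excursion.
    """
    t = np.asarray(t, dtype=float)
    offs = np.asarray(config.phase_offsets)[:, None]
    k = config.steepness

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-k * (x - 50.0 - offs)))

    lo = logistic(np.array([0.0]))
    hi = logistic(np.array([100.0]))
    return (logistic(t[None, :]) - lo) / (hi - lo)


@dataclass(frozen=True)
class _SpineState:
    """Resolved per-level arrays (cranial to caudal) for one configuration."""

    baselines: np.ndarray
    healthy_heights: np.ndarray
    heights: np.ndarray  # current neutral disc heights
    amplitudes: np.ndarray  # apex excursion amplitude (mm)
    pre_heights: np.ndarray
    pre_amplitudes: np.ndarray

    @property
    def s_max(self) -> np.ndarray:
        return 0.5 * self.baselines * (self.heights + self.amplitudes)

    @property
    def delta_s(self) -> np.ndarray:
        return 0.5 * self.baselines * self.amplitudes

    @property
    def ratio(self) -> np.ndarray:
        return self.amplitudes / (self.heights + self.amplitudes)

    @property
    def pre_delta_s(self) -> np.ndarray:
        return 0.5 * self.baselines * self.pre_amplitudes


def _resolve(config: SyntheticSpineConfig) -> _SpineState:
    lvl = list(config.levels)
    b = config.baseline_base_mm * np.asarray(config.size_ratios, dtype=float)
    healthy = np.asarray(config.neutral_disc_heights, dtype=float)
    h = healthy.copy()
    mob = np.ones_like(h)
    for deg in config.degeneration:
        i = lvl.index(deg.level)
        h[i] = max(h[i] - deg.height_loss_mm, 0.5)
        mob[i] = deg.mobility_scale
    A = mob * config.amplitude_fraction * h
    pre_h, pre_A = h.copy(), A.copy()

    if config.device is not None:
        i = lvl.index(config.device.level)
        dev = config.device.device
        h_new = config.device.implanted_height_mm
        h[i] = healthy[i] if h_new is None else float(h_new)
        healthy_range = 0.5 * b[i] * config.amplitude_fraction * healthy[i]
        r_pre = 0.5 * b[i] * pre_A[i]
        r_post = dev.mobility_factor * healthy_range
        A[i] = 2.0 * r_post / b[i]
        removed = r_pre - r_post
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < len(lvl)]
        nbr_ranges = np.array([0.5 * b[j] * pre_A[j] for j in nbrs])
        total = nbr_ranges.sum()
        shares = nbr_ranges / total if total > 0 else np.full(len(nbrs), 1.0 / len(nbrs))
        for j, w in zip(nbrs, shares):
            new_range = max(0.5 * b[j] * pre_A[j] + removed * w, 0.0)
            A[j] = 2.0 * new_range / b[j]
    return _SpineState(b, healthy, h, A, pre_h, pre_A)


@dataclass(frozen=True)
class SpineTruth:
    """Ground truth of a configured spine, for recovery experiments."""

    section: str
    levels: tuple[str, ...]
    baselines: dict[str, float]
    healthy_heights: dict[str, float]
    disc_heights: dict[str, float]
    s_max: dict[str, float]
    delta_s: dict[str, float]
    ratio: dict[str, float]
    target_level: str | None = None
    rom_change: dict[str, float] = field(default_factory=dict)
    mean_adjacent_delta_rom: float = 0.0


def exam_truth(config: SyntheticSpineConfig) -> SpineTruth:
    """Closed-form per-level truth implied by a configuration (no sampling)."""
    state = _resolve(config)
    lvl = config.levels
    as_map = lambda arr: dict(zip(lvl, np.asarray(arr, dtype=float).tolist()))
    target = config.device.level if config.device is not None else None
    rom_change: dict[str, float] = {}
    mean_adj = 0.0
    if target is not None:
        change = np.abs(state.delta_s - state.pre_delta_s)
        rom_change = as_map(change)
        adj = _levels.neighbors(target, lvl)
        mean_adj = float(np.mean([rom_change[a] for a in adj]))
    return SpineTruth(
        config.section,
        lvl,
        as_map(state.baselines),
        as_map(state.healthy_heights),
        as_map(state.heights),
        as_map(state.s_max),
        as_map(state.delta_s),
        as_map(state.ratio),
        target,
        rom_change,
        mean_adj,
    )


def generate_reference_surrogate(
    config: SyntheticSpineConfig | None = None, n_grid: int = 201
) -> ReferenceSurrogate:
    """Healthy reference: normalized per-level curves, heights and size ratios.

    Stands in for literature range-of-motion data.  The curves are expressed
    against the same percentage-of-movement convention the analysis pipeline
    measures (global angle between the most caudal and the most cranial
    available baselines), so patient and reference curves share their axis.
    Deterministic; degeneration or device settings are rejected.
    """
    config = config or SyntheticSpineConfig(noise_sd_fraction=0.0)
    if config.degeneration or config.device is not None:
        raise ConfigError("the reference surrogate describes a healthy spine")
    state = _resolve(config)
    t = np.linspace(0.0, 100.0, n_grid)
    sigma = _sigma_profiles(config, t)
    weights = np.asarray(config.level_weights)
    theta = config.global_arc_deg * (weights[1:, None] * sigma[1:, :]).sum(axis=0)
    frac = 100.0 * (theta - theta[0]) / (theta[-1] - theta[0])
    curves = {}
    for i, lv in enumerate(config.levels):
        area = state.heights[i] + state.amplitudes[i] * sigma[i]
        curves[lv] = MotionCurve(lv, frac, area / area.max(), source=SOURCE_MEASURED)
    heights = dict(zip(config.levels, state.healthy_heights.tolist()))
    ratios = dict(zip(config.levels, map(float, config.size_ratios)))
    return ReferenceSurrogate(config.section, curves, heights, ratios)


def _exam_rng(config: SyntheticSpineConfig, subject_id: str, session_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed) % (2**31), zlib.crc32(subject_id.encode()), zlib.crc32(session_id.encode())]
        )
    )


def _noise_sd_mm(config: SyntheticSpineConfig, state: _SpineState) -> np.ndarray:
    """Per-level landmark noise (mm) inducing area noise of the configured fraction."""
    b = state.baselines
    v_x = _APEX_X_FRACTION * b
    v_y = state.heights + 0.5 * state.amplitudes
    q = 0.5 * (b**2 + v_x**2 + v_y**2 - b * v_x)
    return config.noise_sd_fraction * state.s_max / np.sqrt(q)


def generate_exam(
    config: SyntheticSpineConfig,
    subject_id: str = "S01",
    session_id: str = "A",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, CalibrationRecord]:
    """One functional exam: a landmark table plus its ball calibration.

    Frames sweep the movement parameter uniformly over [0, 100] (endpoints
    are the inclination and reclination poses; an odd frame count includes
    the neutral pose).  A per-frame rigid jitter of the whole section
    exercises the registration without affecting any measured area.
    """
    if rng is None:
        rng = _exam_rng(config, subject_id, session_id)
    state = _resolve(config)
    n = config.n_frames
    t = np.linspace(0.0, 100.0, n)
    sigma = _sigma_profiles(config, t)
    weights = np.asarray(config.level_weights)
    alpha = np.deg2rad(config.global_arc_deg) * weights[:, None] * sigma  # (n_levels, n)

    gamma = rng.normal(0.0, np.deg2rad(2.0), size=n)
    anchor = rng.normal(0.0, 3.0, size=(n, 2))
    scale = config.calibration.scale
    sd_mm = _noise_sd_mm(config, state)

    lvl = config.levels
    n_levels = len(lvl)
    points = {}
    for i in range(n_levels - 1, -1, -1):
        d = np.stack([np.cos(gamma), np.sin(gamma)], axis=1)
        nv = np.stack([-np.sin(gamma), np.cos(gamma)], axis=1)
        b = state.baselines[i]
        y3 = state.heights[i] + state.amplitudes[i] * sigma[i]
        p1 = anchor
        p2 = anchor + b * d
        p3 = anchor + _APEX_X_FRACTION * b * d + y3[:, None] * nv
        points[lvl[i]] = np.stack([p1, p2, p3], axis=1)  # (n, 3, 2)
        anchor = anchor + (y3 + _BODY_HEIGHT_FACTOR * b)[:, None] * nv
        gamma = gamma + alpha[i]

    phase = np.where(
        t == 0.0, "inclination", np.where(t == 100.0, "reclination", np.where(np.abs(t - 50.0) < 1e-9, "neutral", "intermediate"))
    )
    frames_col, phase_col, level_col, pid_col = [], [], [], []
    xs, ys = [], []
    for i, lv in enumerate(lvl):
        P = points[lv] / scale
        if config.noise_sd_fraction > 0:
            P = P + rng.normal(0.0, sd_mm[i] / scale, size=P.shape)
        frames_col.append(np.repeat(np.arange(n), 3))
        phase_col.append(np.repeat(phase, 3))
        level_col.extend([lv] * (3 * n))
        pid_col.append(np.tile([1, 2, 3], n))
        xs.append(P[:, :, 0].ravel())
        ys.append(P[:, :, 1].ravel())
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "session_id": session_id,
            "frame_index": np.concatenate(frames_col),
            "phase": np.concatenate(phase_col),
            "level": level_col,
            "point_id": np.concatenate(pid_col),
            "x_px": np.concatenate(xs),
            "y_px": np.concatenate(ys),
        }
    )
    df = df.sort_values(["frame_index", "level", "point_id"], kind="stable").reset_index(drop=True)
    return df, config.calibration


def generate_identification_cohort(
    template: SyntheticSpineConfig,
    n_subjects: int = 20,
    subject_mobility_sd: float = 0.2,
    phase_jitter: float = 5.0,
    seed: int = 0,
) -> dict[str, tuple[tuple[pd.DataFrame, CalibrationRecord], ...]]:
    """Repeated-measurement cohort: two sessions per subject, distinct spines.

    Between-subject variation enters through per-level mobility scales and
    phase offsets; within-subject variation is only the session landmark
    noise — the setting in which signatures act like fingerprints.
    """
    if n_subjects < 2:
        raise ConfigError("an identification cohort needs >= 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0xB10C]))
    out = {}
    n_levels = len(template.levels)
    for s in range(n_subjects):
        sid = f"S{s + 1:03d}"
        mobility = np.clip(rng.normal(1.0, subject_mobility_sd, n_levels), 0.4, 1.6)
        offsets = np.clip(
            np.asarray(template.phase_offsets) + rng.uniform(-phase_jitter, phase_jitter, n_levels),
            -20.0,
            20.0,
        )
        cfg = replace(
            template,
            degeneration=tuple(
                Degeneration(lv, 0.0, float(m)) for lv, m in zip(template.levels, mobility)
            ),
            phase_offsets=tuple(offsets.tolist()),
        )
        out[sid] = tuple(generate_exam(cfg, sid, ses, rng=rng) for ses in ("A", "B"))
    return out


@dataclass(frozen=True)
class SyntheticCohort:
    """Pre/post exams, ground truths and outcome scores for many subjects."""

    section: str
    target_level: str
    exams: dict[tuple[str, str], tuple[pd.DataFrame, CalibrationRecord]]
    truths: dict[str, SpineTruth]
    outcomes: tuple[OutcomeRecord, ...]
    outcome_model: OutcomeModel
    seed: int

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted(self.truths))


def generate_cohort(
    template: SyntheticSpineConfig,
    n_subjects: int,
    outcome_model: OutcomeModel | None = None,
    seed: int = 0,
    mobility_range: tuple[float, float] = (1.2, 1.8),
    height_loss_range: tuple[float, float] = (0.5, 2.0),
) -> SyntheticCohort:
    """Implant cohort: randomized target instability, pre and post exams.

    The template must carry a device; the surgical target is its level,
    modelled as an unstable hypermobile segment with some disc-height loss
    (the fusion indication).  Outcome worsening follows the outcome model
    from each subject's true mean adjacent dRoM.
    """
    if n_subjects < 2:
        raise ConfigError("a cohort needs >= 2 subjects")
    if template.device is None:
        raise ConfigError("the cohort template must specify an implanted device")
    outcome_model = outcome_model or OutcomeModel()
    target = template.device.level
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0xC0407]))
    exams = {}
    truths = {}
    outcomes = []
    for s in range(n_subjects):
        sid = f"S{s + 1:03d}"
        deg = Degeneration(
            target,
            float(rng.uniform(*height_loss_range)),
            float(rng.uniform(*mobility_range)),
        )
        pre_cfg = replace(template, degeneration=(deg,), device=None)
        post_cfg = replace(pre_cfg, device=template.device)
        exams[(sid, "pre")] = generate_exam(pre_cfg, sid, "pre", rng=rng)
        exams[(sid, "post")] = generate_exam(post_cfg, sid, "post", rng=rng)
        truth = exam_truth(post_cfg)
        truths[sid] = truth
        worsening = outcome_model.slope * truth.mean_adjacent_delta_rom + rng.normal(
            0.0, outcome_model.noise_sd
        )
        pre_score = outcome_model.baseline_pre
        post_score = float(np.clip(pre_score + worsening, 0.0, 1.0))
        outcomes.append(OutcomeRecord(sid, outcome_model.score_name, pre_score, post_score))
    return SyntheticCohort(
        template.section, target, exams, truths, tuple(outcomes), outcome_model, seed
    )
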