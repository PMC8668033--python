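"""High-level workflows chaining geometry, motion, signature and planning.

These are the analysis chains the command-line interface exposes: a full
single-exam analysis, a pre/post comparison, an implant recommendation, and
the repeated-measurement reproducibility study.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import levels as _levels
from .errors import MissingUpperPlateError
from .io import ExamBundle
from .motion import MotionCurve, build_rom_curve, conventional_rom, interpolate_curve
from .planning import (
    DeviceSpec,
    ImplantPlan,
    delta_rom,
    map_to_device_grid,
    optimal_device_height,
    predict_postop_curves,
    virtual_substitution,
)
from .signature import (
    ReferenceSurrogate,
    ReproducibilityReport,
    bayes_error_rate,
    detect_best_segment,
    detect_worst_segment,
    estimate_disc_height,
    spine_signature,
)

__all__ = [
    "exam_curves",
    "exam_signature",
    "analyze_exam",
    "compare_exams",
    "recommend_plan",
    "reproducibility_study",
]


def exam_curves(bundle: ExamBundle, densify: int | None = 101) -> dict[str, MotionCurve]:
    """Measured RoM curves per level; sparse 3-pose exams are densified."""
    frames = bundle.frames()
    curves = {}
    for lv in frames[0].triangles:
        c = build_rom_curve(frames, lv)
        if densify and len(c) >= 3 and len(c) < densify:
            c = interpolate_curve(c, densify)
        curves[lv] = c
    return curves


def exam_signature(bundle: ExamBundle):
    """Section signature of one exam (from the measured, un-densified curves)."""
    frames = bundle.frames()
    curves = {lv: build_rom_curve(frames, lv) for lv in frames[0].triangles}
    return spine_signature(curves, bundle.section)


def _baselines(bundle: ExamBundle) -> dict[str, float]:
    frames = bundle.frames()
    return {
        lv: float(np.mean([f.triangles[lv].baseline_length for f in frames]))
        for lv in frames[0].triangles
    }


def _heights(
    curves: Mapping[str, MotionCurve],
    baselines: Mapping[str, float],
    reference: ReferenceSurrogate | None,
) -> dict[str, float]:
    return {
        lv: estimate_disc_height(
            c, baselines[lv], reference.curves.get(lv) if reference else None
        )
        for lv, c in curves.items()
    }


def analyze_exam(bundle: ExamBundle, reference: ReferenceSurrogate) -> dict:
    """Signatures, curves, conventional ROM, worst/best detection for one exam."""
    frames = bundle.frames()
    raw = {lv: build_rom_curve(frames, lv) for lv in frames[0].triangles}
    curves = {lv: interpolate_curve(c, 101) if 3 <= len(c) < 101 else c for lv, c in raw.items()}
    sig = spine_signature(raw, bundle.section)
    conventional = {}
    for lv in raw:
        try:
            conventional[lv] = conventional_rom(frames, lv)
        except MissingUpperPlateError:
            conventional[lv] = None
    baselines = _baselines(bundle)
    heights = _heights(curves, baselines, reference)
    worst = detect_worst_segment(curves, reference)
    best = detect_best_segment(curves, heights, reference, exclude={worst.level})
    return {
        "subject_id": bundle.subject_id,
        "session_id": bundle.session_id,
        "section": bundle.section,
        "curves": curves,
        "signature": sig,
        "signature_ratios": dict(zip(sig.levels, sig.ratios.tolist())),
        "conventional_rom_deg": conventional,
        "disc_heights_mm": heights,
        "worst_level": worst.level,
        "worst_deviations": worst.deviations,
        "worst_tie": worst.tie,
        "best_level": best.level,
        "best_scores": best.scores,
    }


def compare_exams(pre: ExamBundle, post: ExamBundle) -> list:
    """Per-level dRoM between two exams of the same subject."""
    pre_curves = {lv: c for lv, c in exam_curves(pre, densify=None).items()}
    post_curves = {lv: c for lv, c in exam_curves(post, densify=None).items()}
    shared = _levels.ordered_levels(set(pre_curves) & set(post_curves))
    return [delta_rom(pre_curves[lv], post_curves[lv]) for lv in shared]


def recommend_plan(
    bundle: ExamBundle,
    reference: ReferenceSurrogate,
    device: DeviceSpec,
    target: str | None = None,
) -> ImplantPlan:
    """Full implant recommendation for one exam.

    The surgeon may force the target level; otherwise the worst segment is
    detected automatically.
    """
    report = analyze_exam(bundle, reference)
    curves = report["curves"]
    worst = target or report["worst_level"]
    best = (
        report["best_level"]
        if worst == report["worst_level"]
        else detect_best_segment(
            curves, report["disc_heights_mm"], reference, exclude={worst}
        ).level
    )
    substitution = virtual_substitution(curves, worst, best, reference)
    rec = optimal_device_height(report["disc_heights_mm"], worst, best, reference)
    grid_height, exact = map_to_device_grid(rec.height_mm, device)
    prediction = predict_postop_curves(curves, worst, device, reference)
    changes = tuple(
        delta_rom(curves[lv], prediction.curves[lv]) for lv in _levels.ordered_levels(curves)
    )
    return ImplantPlan(
        target_level=worst,
        best_level=best,
        recommended_height=rec.height_mm,
        grid_height=grid_height,
        exact_available=exact,
        capped=rec.capped,
        device=device,
        virtual_substitution_curve=substitution,
        virtual_curves=prediction.curves,
        delta_rom_per_level=changes,
    )


def reproducibility_study(
    bundles: Sequence[ExamBundle],
    n_draws: int = 100_000,
    rng=None,
) -> tuple[ReproducibilityReport, dict]:
    """Methods-style reproducibility: two sessions per subject, Bayes error.

    Returns the report plus the per-subject/session signatures used.
    """
    by_subject: dict[str, dict[str, ExamBundle]] = {}
    for b in bundles:
        by_subject.setdefault(b.subject_id, {})[b.session_id] = b
    signatures = {}
    repeated = {}
    for sid, sessions in by_subject.items():
        keys = sorted(sessions)
        sigs = tuple(exam_signature(sessions[k]) for k in keys)
        for k, s in zip(keys, sigs):
            signatures[(sid, k)] = s
        if len(sigs) == 2:
            repeated[sid] = sigs
    report = bayes_error_rate(repeated, n_draws=n_draws, rng=rng)
    return report, signatures
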