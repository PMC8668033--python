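"""Readers and writers for the defined text formats.

Landmark tables are comma-separated with the header
``subject_id,session_id,frame_index,phase,level,point_id,x_px,y_px``;
calibration records, device specifications, reference surrogates and reports
are JSON documents; curves and signatures export as CSV.  Writers and
readers are exact inverses on well-formed inputs.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__, levels as _levels
from .errors import SchemaError
from .geometry import CalibrationRecord, calibrate_scale
from .motion import PHASES, MotionCurve, MotionFrame, frames_from_landmarks
from .planning import DeviceSpec, OutcomeRecord, RoMChange
from .signature import ReferenceSurrogate, ReproducibilityReport, SpineSignature
from .synthetic import LANDMARK_COLUMNS, SyntheticCohort

__all__ = [
    "ExamBundle",
    "read_landmark_table",
    "write_landmark_table",
    "read_calibration",
    "write_calibration",
    "load_exams",
    "read_curves",
    "write_curves",
    "read_reference",
    "write_reference",
    "read_device",
    "write_device",
    "read_outcomes",
    "write_outcomes",
    "write_signatures",
    "write_report",
    "write_delta_rom_table",
    "write_cohort",
]

REQUIRED_COLUMNS = LANDMARK_COLUMNS


def read_landmark_table(path) -> pd.DataFrame:
    """Read and validate a landmark table.

    Unknown columns are preserved but ignored; phases are validated; numeric
    columns are checked row by row so errors can name the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty landmark table") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: landmark table has no rows")
    for col in ("frame_index", "point_id", "x_px", "y_px"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced
    df["frame_index"] = df["frame_index"].astype(int)
    df["point_id"] = df["point_id"].astype(int)
    unknown_phases = set(df["phase"].unique()) - set(PHASES)
    if unknown_phases:
        raise SchemaError(f"{path}: unknown phase value(s) {sorted(unknown_phases)}")
    return df


def write_landmark_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)


def read_calibration(path) -> CalibrationRecord:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        return calibrate_scale(doc["ball_true_diameter_mm"], doc["ball_image_diameter_px"])
    except KeyError as exc:
        raise SchemaError(f"{path}: calibration record missing {exc}") from None


def write_calibration(record: CalibrationRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "ball_true_diameter_mm": record.ball_true_diameter_mm,
                "ball_image_diameter_px": record.ball_image_diameter_px,
            },
            fh,
            indent=2,
        )


@dataclass
class ExamBundle:
    """One subject/session exam: landmarks plus calibration."""

    subject_id: str
    session_id: str
    landmarks: pd.DataFrame
    calibration: CalibrationRecord
    section: str

    def frames(self) -> list[MotionFrame]:
        return frames_from_landmarks(self.landmarks, self.calibration, self.section)


def load_exams(landmarks_path, calibration_path, section: str | None = None) -> list[ExamBundle]:
    """Load a landmark file into one bundle per (subject, session)."""
    df = read_landmark_table(landmarks_path)
    calibration = read_calibration(calibration_path)
    section = section or _levels.infer_section(df["level"].unique())
    bundles = []
    for (sid, ses), grp in df.groupby(["subject_id", "session_id"], sort=True):
        bundles.append(ExamBundle(str(sid), str(ses), grp.reset_index(drop=True), calibration, section))
    return bundles


def write_curves(curves: Iterable[MotionCurve], path) -> None:
    rows = []
    for c in curves:
        for f, a in zip(c.fraction, c.area):
            rows.append((c.level, f, a, c.source))
    pd.DataFrame(rows, columns=["level", "fraction", "area_mm2", "source"]).to_csv(path, index=False)


def read_curves(path) -> dict[str, MotionCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"level", "fraction", "area_mm2", "source"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing curve column(s) {sorted(missing)}")
    out = {}
    for lv, grp in df.groupby("level", sort=False):
        grp = grp.sort_values("fraction")
        out[str(lv)] = MotionCurve(
            str(lv),
            grp["fraction"].to_numpy(),
            grp["area_mm2"].to_numpy(),
            source=str(grp["source"].iloc[0]),
        )
    return out


def write_reference(reference: ReferenceSurrogate, path) -> None:
    doc = {
        "section": reference.section,
        "levels": {
            lv: {
                "fraction": reference.curves[lv].fraction.tolist(),
                "area": reference.curves[lv].area.tolist(),
                "neutral_height_mm": reference.neutral_heights[lv],
                "size_ratio": reference.size_ratios[lv],
            }
            for lv in reference.levels
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_reference(path) -> ReferenceSurrogate:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        curves = {
            lv: MotionCurve(lv, np.array(entry["fraction"]), np.array(entry["area"]))
            for lv, entry in doc["levels"].items()
        }
        heights = {lv: float(e["neutral_height_mm"]) for lv, e in doc["levels"].items()}
        ratios = {lv: float(e["size_ratio"]) for lv, e in doc["levels"].items()}
        return ReferenceSurrogate(doc["section"], curves, heights, ratios)
    except KeyError as exc:
        raise SchemaError(f"{path}: reference surrogate missing {exc}") from None


def read_device(path) -> DeviceSpec:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        return DeviceSpec(
            doc["name"],
            doc["kind"],
            float(doc.get("mobility_factor", 0.0)),
            tuple(doc["available_heights_mm"]),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: device config missing {exc}") from None


def write_device(device: DeviceSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "name": device.name,
                "kind": device.kind,
                "mobility_factor": device.mobility_factor,
                "available_heights_mm": list(device.available_heights),
            },
            fh,
            indent=2,
        )


def read_outcomes(path) -> list[OutcomeRecord]:
    df = pd.read_csv(path)
    missing = {"subject_id", "score_name", "pre", "post"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing outcome column(s) {sorted(missing)}")
    return [
        OutcomeRecord(str(r.subject_id), str(r.score_name), float(r.pre), float(r.post))
        for r in df.itertuples()
    ]


def write_outcomes(outcomes: Iterable[OutcomeRecord], path) -> None:
    pd.DataFrame(
        [(o.subject_id, o.score_name, o.pre, o.post) for o in outcomes],
        columns=["subject_id", "score_name", "pre", "post"],
    ).to_csv(path, index=False)


def write_signatures(signatures: Mapping[tuple[str, str], SpineSignature], path) -> None:
    """Export ``(subject, session) -> SpineSignature`` as the signature CSV."""
    rows = []
    for (sid, ses), sig in signatures.items():
        for s in sig.signatures:
            rows.append((sid, ses, s.level, s.delta_s, s.s_max, s.ratio))
    pd.DataFrame(
        rows, columns=["subject_id", "session_id", "level", "delta_s_mm2", "s_max_mm2", "ratio"]
    ).to_csv(path, index=False)


def write_delta_rom_table(changes: Iterable[RoMChange], path) -> None:
    pd.DataFrame(
        [(c.level, c.pre_range, c.post_range, c.delta_rom) for c in changes],
        columns=["level", "pre_range_mm2", "post_range_mm2", "delta_rom_mm2"],
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (ReproducibilityReport, RoMChange)):
        return _jsonable(asdict(obj))
    return obj


def write_report(document: Mapping, path, seed: int | None = None) -> None:
    """Write an analysis report with tool version and seed always present."""
    doc = {"tool": "biokin", "version": __version__, "seed": seed}
    doc.update(_jsonable(document))
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def write_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Write a synthetic cohort to disk; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "section": cohort.section,
        "target_level": cohort.target_level,
        "seed": cohort.seed,
        "subjects": {},
    }
    any_calibration = None
    for (sid, arm), (df, calibration) in sorted(cohort.exams.items()):
        name = f"landmarks_{sid}_{arm}.csv"
        write_landmark_table(df, directory / name)
        manifest["subjects"].setdefault(sid, {})[arm] = name
        any_calibration = calibration
    if any_calibration is not None:
        write_calibration(any_calibration, directory / "calibration.json")
    write_outcomes(cohort.outcomes, directory / "outcomes.csv")
    truth_doc = {
        sid: {
            "disc_heights": t.disc_heights,
            "healthy_heights": t.healthy_heights,
            "delta_s": t.delta_s,
            "ratio": t.ratio,
            "rom_change": t.rom_change,
            "mean_adjacent_delta_rom": t.mean_adjacent_delta_rom,
        }
        for sid, t in cohort.truths.items()
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(_jsonable(truth_doc), fh, indent=2)
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
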