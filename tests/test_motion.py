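import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biokin.errors import (
    IncompleteCurveError,
    IncompleteLevelError,
    InsufficientFamilyError,
    InsufficientKnotsError,
    MissingPoseError,
    MissingUpperPlateError,
    OutOfRangeFractionWarning,
    ZeroArcError,
)
from biokin.geometry import BiokinemetricTriangle
from biokin.motion import (
    MotionCurve,
    MotionFrame,
    build_rom_curve,
    conventional_rom,
    frames_from_landmarks,
    interpolate_curve,
    motion_surface,
    movement_fraction,
)


def _tri(level, apex_y):
    return BiokinemetricTriangle(level, (0.0, 0.0), (30.0, 0.0), (12.0, apex_y))


def _frame(idx, phase, angle, apex_by_level, dirs=None):
    tris = {lv: _tri(lv, y) for lv, y in apex_by_level.items()}
    return MotionFrame(idx, phase, angle, tris, dirs or {})


def make_frames(angles=(-40.0, -5.0, 30.0), apexes=(8.0, 6.5, 5.5), level="C5-C6"):
    phases = ["inclination"] + ["intermediate"] * (len(angles) - 2) + ["reclination"]
    if len(angles) == 3:
        phases[1] = "neutral"
    return [
        _frame(i, ph, a, {level: y})
        for i, (ph, a, y) in enumerate(zip(phases, angles, apexes))
    ]


class TestMovementFraction:
    def test_endpoints_and_midpoint(self):
        frames = make_frames()
        frac = movement_fraction(frames)
        # -40 -> 0 %, -5 is the midpoint of the 70 degree arc, +30 -> 100 %
        assert np.allclose(frac, [0.0, 50.0, 100.0])

    def test_zero_arc_rejected(self):
        frames = make_frames(angles=(10.0, 10.0, 10.0))
        with pytest.raises(ZeroArcError):
            movement_fraction(frames)

    def test_out_of_range_intermediate_clamped_with_warning(self):
        frames = make_frames(angles=(-40.0, -45.0, 30.0))
        with pytest.warns(OutOfRangeFractionWarning):
            frac = movement_fraction(frames)
        assert frac[1] == 0.0

    def test_missing_endpoint_pose(self):
        frames = make_frames()
        frames[-1].phase = "intermediate"
        with pytest.raises(MissingPoseError):
            movement_fraction(frames)

    @given(shift=st.floats(-90.0, 90.0))
    def test_translation_invariance_in_global_angle(self, shift):
        base = movement_fraction(make_frames())
        shifted = movement_fraction(make_frames(angles=(-40.0 + shift, -5.0 + shift, 30.0 + shift)))
        assert np.allclose(base, shifted, atol=1e-9)


class TestBuildRomCurve:
    def test_max_min_and_ordering(self):
        curve = build_rom_curve(make_frames(apexes=(8.0, 20.0 / 3.0, 17.0 / 3.0)), "C5-C6")
        assert curve.s_max == pytest.approx(120.0)
        assert curve.s_min == pytest.approx(85.0)
        assert np.all(np.diff(curve.fraction) > 0)

    def test_unordered_frames_give_same_curve(self):
        frames = make_frames()
        shuffled = [frames[1], frames[2], frames[0]]
        a = build_rom_curve(frames, "C5-C6")
        b = build_rom_curve(shuffled, "C5-C6")
        assert np.allclose(a.fraction, b.fraction)
        assert np.allclose(a.area, b.area)

    def test_single_frame_rejected(self):
        with pytest.raises(IncompleteCurveError):
            build_rom_curve(make_frames()[:1], "C5-C6")

    def test_missing_level_rejected(self):
        with pytest.raises(IncompleteLevelError):
            build_rom_curve(make_frames(), "C2-C3")

    def test_duplicate_fractions_averaged(self):
        frames = make_frames(angles=(-40.0, -40.0, 30.0), apexes=(8.0, 6.0, 5.0))
        curve = build_rom_curve(frames, "C5-C6")
        assert len(curve) == 2
        assert curve.area[0] == pytest.approx(0.5 * 30 * 7.0)  # mean of 8 and 6 apexes


class TestInterpolation:
    def _sparse(self):
        return MotionCurve("C5-C6", [0.0, 50.0, 100.0], [120.0, 100.0, 85.0])

    def test_knots_reproduced_exactly(self):
        dense = interpolate_curve(self._sparse(), 101)
        for f, a in zip([0.0, 50.0, 100.0], [120.0, 100.0, 85.0]):
            assert dense.area[dense.fraction == f][0] == pytest.approx(a, abs=1e-9)

    def test_no_overshoot_between_knots(self):
        dense = interpolate_curve(self._sparse(), 101)
        assert dense.area.max() <= 120.0 + 1e-9
        assert dense.area.min() >= 85.0 - 1e-9
        assert dense.source == "interpolated"

    def test_linear_knots_reproduce_the_line(self):
        sparse = MotionCurve("C5-C6", [0.0, 40.0, 100.0], [10.0, 18.0, 30.0])
        dense = interpolate_curve(sparse, 51)
        assert np.allclose(dense.area, 10.0 + 0.2 * dense.fraction, atol=1e-9)

    def test_refinement_consistency(self):
        sparse = self._sparse()
        coarse = interpolate_curve(sparse, 51)
        fine = interpolate_curve(sparse, 101)
        shared = np.intersect1d(coarse.fraction, fine.fraction)
        assert shared.size >= 51
        a = coarse.area[np.isin(coarse.fraction, shared)]
        b = fine.area[np.isin(fine.fraction, shared)]
        assert np.allclose(a, b, atol=1e-9)

    def test_two_knots_rejected(self):
        with pytest.raises(InsufficientKnotsError):
            interpolate_curve(MotionCurve("C5-C6", [0.0, 100.0], [1.0, 2.0]), 11)


class TestConventionalRom:
    def _frames(self):
        frames = []
        for i, (phase, low, up) in enumerate(
            [("inclination", 0.0, -6.0), ("neutral", 0.0, 1.0), ("reclination", 0.0, 8.0)]
        ):
            dirs = {
                "C5-C6": np.array([np.cos(np.radians(low)), np.sin(np.radians(low))]),
                "C4-C5": np.array([np.cos(np.radians(up)), np.sin(np.radians(up))]),
            }
            frames.append(
                _frame(i, phase, float(up), {"C5-C6": 6.0, "C4-C5": 6.0}, dirs)
            )
        return frames

    def test_signed_difference(self):
        assert conventional_rom(self._frames(), "C5-C6") == pytest.approx(14.0)

    def test_antisymmetric_under_pose_swap(self):
        frames = self._frames()
        frames[0].phase, frames[-1].phase = "reclination", "inclination"
        assert conventional_rom(frames, "C5-C6") == pytest.approx(-14.0)

    def test_missing_reclination_pose(self):
        frames = self._frames()
        frames[-1].phase = "intermediate"
        with pytest.raises(MissingPoseError):
            conventional_rom(frames, "C5-C6")

    def test_topmost_level_needs_supplied_upper_plate(self):
        with pytest.raises(MissingUpperPlateError):
            conventional_rom(self._frames(), "C4-C5")


class TestMotionSurface:
    def _family(self, shape):
        f = np.linspace(0.0, 100.0, 81)
        return {o: MotionCurve("C5-C6", f, shape(f, o)) for o in (-10.0, 0.0, 10.0)}

    def test_logistic_curvature_extrema_match_closed_form(self):
        k = 0.15
        surf = motion_surface(
            self._family(lambda f, o: 50.0 / (1.0 + np.exp(-k * (f - 50.0)))), "C5-C6"
        )
        assert not surf.indeterminate
        # |S''| of a logistic peaks at 50 +/- ln(2 + sqrt(3)) / k, symmetric
        # about the inflection; the numeric locus must hit one of the pair
        offset = np.log(2.0 + np.sqrt(3.0)) / k
        assert (
            min(
                abs(surf.curvature_max_location - (50.0 - offset)),
                abs(surf.curvature_max_location - (50.0 + offset)),
            )
            < 2.5
        )

    @pytest.mark.parametrize("shape", [lambda f, o: np.full_like(f, 30.0), lambda f, o: 10.0 + 0.1 * f])
    def test_flat_and_linear_curves_are_indeterminate(self, shape):
        surf = motion_surface(self._family(shape), "C5-C6")
        assert surf.indeterminate
        assert np.isnan(surf.curvature_max_location)

    def test_fewer_than_three_curves_rejected(self):
        f = np.linspace(0, 100, 11)
        fam = {0.0: MotionCurve("C5-C6", f, f + 1.0)}
        with pytest.raises(InsufficientFamilyError):
            motion_surface(fam, "C5-C6")


class TestFramesFromLandmarks:
    def test_pipeline_frames_carry_all_levels(self, clean_exam, zero_noise_config):
        df, calibration = clean_exam
        frames = frames_from_landmarks(df, calibration)
        assert len(frames) == zero_noise_config.n_frames
        assert set(frames[0].triangles) == set(zero_noise_config.levels)
        assert frames[0].phase == "inclination"
        assert frames[-1].phase == "reclination"

    def test_missing_rows_rejected(self, clean_exam):
        df, calibration = clean_exam
        broken = df.iloc[:-1]
        with pytest.raises((IncompleteLevelError, IncompleteCurveError)):
            frames_from_landmarks(broken, calibration)
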