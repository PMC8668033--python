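import numpy as np
import pytest

from biokin.errors import (
    ConfigError,
    DegenerateSubstitutionError,
    EmptyGridError,
    InsufficientCohortError,
    InvalidHeightError,
    LevelMismatchError,
)
from biokin.motion import MotionCurve
from biokin.planning import (
    DeviceSpec,
    OutcomeRecord,
    correlate_delta_rom_outcome,
    delta_rom,
    map_to_device_grid,
    optimal_device_height,
    predict_postop_curves,
    virtual_substitution,
)
from biokin.synthetic import Degeneration, SyntheticSpineConfig, generate_exam
from biokin.motion import build_rom_curve, frames_from_landmarks


def curve(level, areas):
    return MotionCurve(level, np.linspace(0, 100, len(areas)), areas)


@pytest.fixture(scope="module")
def hypermobile_curves(reference):
    """Zero-noise exam with an unstable hypermobile C4-C5 segment."""
    cfg = SyntheticSpineConfig(
        noise_sd_fraction=0.0,
        degeneration=(Degeneration("C4-C5", height_loss_mm=0.5, mobility_scale=1.6),),
        seed=3,
    )
    df, calibration = generate_exam(cfg, "S", "A")
    frames = frames_from_landmarks(df, calibration, cfg.section)
    return {lv: build_rom_curve(frames, lv) for lv in frames[0].triangles}


class TestDeviceSpec:
    def test_cage_forced_rigid(self):
        dev = DeviceSpec("C", "cage", 0.7, (5.0, 6.0))
        assert dev.mobility_factor == 0.0

    def test_unsorted_heights_rejected(self):
        with pytest.raises(ConfigError):
            DeviceSpec("P", "prosthesis", 0.5, (6.0, 5.0))


class TestVirtualSubstitution:
    def test_identity_substitution_with_equal_size_ratio(self, reference):
        patient = dict(reference.curves)
        out = virtual_substitution(patient, "C2-C3", "C5-C6", reference)
        quotient = reference.size_ratios["C2-C3"] / reference.size_ratios["C5-C6"]
        assert out.level == "C2-C3"
        assert out.source == "virtual"
        assert np.allclose(out.area, patient["C5-C6"].area * quotient)

    def test_signature_ratio_transfers(self, reference):
        donor = curve("C5-C6", [100.0, 80.0, 60.0])
        patient = {"C5-C6": donor, "C6-C7": curve("C6-C7", [50.0, 50.0, 50.0])}
        out = virtual_substitution(patient, "C6-C7", "C5-C6", reference)
        assert (out.s_max - out.s_min) / out.s_max == pytest.approx(0.4)

    def test_worst_equals_best_rejected(self, reference):
        with pytest.raises(DegenerateSubstitutionError):
            virtual_substitution(dict(reference.curves), "C5-C6", "C5-C6", reference)


class TestOptimalHeight:
    def test_equal_ratios_carry_height_over(self, reference):
        heights = {lv: reference.neutral_heights[lv] for lv in reference.levels}
        heights["C5-C6"] = 4.0  # collapsed target
        rec = optimal_device_height(heights, "C5-C6", "C3-C4", reference)
        quotient = reference.size_ratios["C5-C6"] / reference.size_ratios["C3-C4"]
        expected = min(heights["C3-C4"] * quotient, reference.neutral_heights["C5-C6"])
        assert rec.height_mm == pytest.approx(expected)
        assert not rec.no_change

    def test_cap_prevents_overcorrection(self, reference):
        heights = {lv: 2.0 * reference.neutral_heights[lv] for lv in reference.levels}
        heights["C5-C6"] = 4.0
        rec = optimal_device_height(heights, "C5-C6", "C3-C4", reference)
        assert rec.capped
        assert rec.height_mm == pytest.approx(reference.neutral_heights["C5-C6"])

    def test_no_change_flag_when_target_already_tall(self, reference):
        heights = {lv: reference.neutral_heights[lv] for lv in reference.levels}
        heights["C5-C6"] = 99.0
        rec = optimal_device_height(heights, "C5-C6", "C3-C4", reference)
        assert rec.no_change

    def test_nonpositive_height_rejected(self, reference):
        heights = {lv: reference.neutral_heights[lv] for lv in reference.levels}
        heights["C3-C4"] = 0.0
        with pytest.raises(InvalidHeightError):
            optimal_device_height(heights, "C5-C6", "C3-C4", reference)


class TestDeviceGrid:
    def test_documented_half_millimetre_scenario(self):
        # a 4.5 mm recommendation against a grid that only starts at 5 mm
        dev = DeviceSpec("P", "prosthesis", 0.8, (5.0, 6.0, 7.0))
        assert map_to_device_grid(4.5, dev) == (5.0, False)

    def test_exact_hit(self):
        dev = DeviceSpec("P", "prosthesis", 0.8, (5.0, 6.0, 7.0))
        assert map_to_device_grid(5.0, dev) == (5.0, True)

    def test_tie_breaks_to_smaller_height(self):
        dev = DeviceSpec("P", "prosthesis", 0.8, (5.0, 6.0))
        assert map_to_device_grid(5.5, dev) == (5.0, False)

    def test_empty_grid_rejected(self):
        dev = DeviceSpec("P", "prosthesis", 0.8, ())
        with pytest.raises(EmptyGridError):
            map_to_device_grid(5.0, dev)


class TestPostopPrediction:
    def test_identity_device_on_reference_range_changes_nothing(self, reference):
        patient = {lv: MotionCurve(lv, c.fraction, 80.0 * c.area) for lv, c in reference.curves.items()}
        dev = DeviceSpec("P", "prosthesis", 1.0, (6.0,))
        pred = predict_postop_curves(patient, "C4-C5", dev, reference)
        for lv in patient:
            assert np.allclose(pred.curves[lv].area, patient[lv].area, atol=1e-9)

    def test_cage_zeroes_target_and_conserves_total(self, hypermobile_curves, reference):
        dev = DeviceSpec("C", "cage", 0.0, (6.0,))
        pred = predict_postop_curves(hypermobile_curves, "C4-C5", dev, reference)
        assert pred.curves["C4-C5"].delta_s == pytest.approx(0.0, abs=1e-9)
        total_pre = sum(c.delta_s for c in hypermobile_curves.values())
        total_post = sum(c.delta_s for c in pred.curves.values())
        assert abs(total_post - total_pre) / total_pre < 1e-9

    def test_adjacent_drom_non_increasing_in_mobility(self, hypermobile_curves, reference):
        means = []
        for f in np.arange(0.0, 1.0001, 0.2):
            kind = "cage" if f == 0 else "prosthesis"
            pred = predict_postop_curves(
                hypermobile_curves, "C4-C5", DeviceSpec("D", kind, float(f), (6.0,)), reference
            )
            changes = [
                delta_rom(hypermobile_curves[lv], pred.curves[lv]).delta_rom
                for lv in pred.neighbor_shares
            ]
            means.append(np.mean(changes))
        assert np.all(np.diff(means) <= 1e-9)
        assert means[0] >= max(means[1:])  # the rigid cage dominates

    def test_boundary_target_flags_single_neighbor(self, hypermobile_curves, reference):
        dev = DeviceSpec("C", "cage", 0.0, (6.0,))
        pred = predict_postop_curves(hypermobile_curves, "C2-C3", dev, reference)
        assert pred.single_neighbor
        assert list(pred.neighbor_shares) == ["C3-C4"]

    def test_prediction_is_idempotent(self, hypermobile_curves, reference):
        dev = DeviceSpec("P", "prosthesis", 0.6, (6.0,))
        once = predict_postop_curves(hypermobile_curves, "C4-C5", dev, reference)
        twice = predict_postop_curves(once.curves, "C4-C5", dev, reference)
        for lv in hypermobile_curves:
            assert np.allclose(twice.curves[lv].area, once.curves[lv].area, atol=1e-9)

    def test_worst_and_best_never_coincide_in_workflow(self, hypermobile_curves, reference):
        from biokin.signature import detect_best_segment, detect_worst_segment

        worst = detect_worst_segment(hypermobile_curves, reference)
        heights = {lv: reference.neutral_heights[lv] for lv in hypermobile_curves}
        best = detect_best_segment(
            hypermobile_curves, heights, reference, exclude={worst.level}
        )
        assert worst.level != best.level


class TestDeltaRom:
    def test_absolute_difference(self):
        pre = curve("C4-C5", [100.0, 60.0])
        post = curve("C4-C5", [100.0, 75.0])
        change = delta_rom(pre, post)
        assert change.delta_rom == pytest.approx(15.0)
        assert delta_rom(post, pre).delta_rom == pytest.approx(15.0)

    def test_identical_curves_give_zero(self):
        pre = curve("C4-C5", [100.0, 60.0])
        assert delta_rom(pre, pre).delta_rom == 0.0

    def test_level_mismatch_rejected(self):
        with pytest.raises(LevelMismatchError):
            delta_rom(curve("C4-C5", [1.0, 2.0]), curve("C5-C6", [1.0, 2.0]))


class TestOutcomeCorrelation:
    def test_perfect_anticorrelation(self):
        droms = {f"s{i}": float(i) for i in range(6)}
        outcomes = {f"s{i}": 0.02 * i for i in range(6)}  # worsening rises with dRoM
        res = correlate_delta_rom_outcome(droms, outcomes, n_permutations=500, rng=0)
        assert res.r == pytest.approx(-1.0)
        assert res.p_value < 0.05

    def test_matches_scipy_pearson(self, rng):
        droms = {f"s{i}": float(v) for i, v in enumerate(rng.normal(20, 4, 12))}
        deltas = {f"s{i}": float(v) for i, v in enumerate(rng.normal(0.05, 0.02, 12))}
        res = correlate_delta_rom_outcome(droms, deltas, n_permutations=200, rng=0)
        from scipy.stats import pearsonr

        expected = pearsonr(
            [droms[f"s{i}"] for i in range(12)], [-deltas[f"s{i}"] for i in range(12)]
        )
        assert res.r == pytest.approx(expected.statistic, abs=1e-12)

    def test_constant_outcome_flagged_undefined(self):
        droms = {f"s{i}": float(i) for i in range(5)}
        outcomes = {f"s{i}": 0.1 for i in range(5)}
        res = correlate_delta_rom_outcome(droms, outcomes, n_permutations=100, rng=0)
        assert res.undefined and np.isnan(res.r)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InsufficientCohortError):
            correlate_delta_rom_outcome({"a": 1.0, "b": 2.0}, {"a": 0.1, "b": 0.2})

    def test_outcome_record_bounds(self):
        with pytest.raises(ConfigError):
            OutcomeRecord("s1", "NDI", 0.4, 1.4)
        rec = OutcomeRecord("s1", "NRS_neck", 4.0, 2.5)
        assert rec.delta == pytest.approx(-1.5)
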