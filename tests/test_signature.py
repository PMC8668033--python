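import numpy as np
import pytest
from scipy.stats import norm

from biokin.errors import (
    DuplicateLevelError,
    IncompatibleSignatureError,
    IncompleteSectionError,
    InsufficientCohortError,
    NoCandidateError,
    ReferenceGapError,
)
from biokin.levels import CERVICAL_LEVELS
from biokin.motion import MotionCurve
from biokin.signature import (
    SpineSignature,
    bayes_error_rate,
    detect_best_segment,
    detect_worst_segment,
    estimate_disc_height,
    gaussian_bayes_error,
    segment_signature,
    signature_distance,
    spine_signature,
)


def curve(level, areas, fractions=None):
    if fractions is None:
        fractions = np.linspace(0.0, 100.0, len(areas))
    return MotionCurve(level, fractions, areas)


def cervical_signature(ratios):
    curves = {
        lv: curve(lv, [100.0, 100.0 * (1.0 - r)]) for lv, r in zip(CERVICAL_LEVELS, ratios)
    }
    return spine_signature(curves, "cervical")


class TestSegmentSignature:
    def test_ratio_from_definition(self):
        s = segment_signature(curve("C5-C6", [100.0, 80.0, 60.0]))
        assert s.delta_s == pytest.approx(40.0)
        assert s.ratio == pytest.approx(0.4)

    def test_constant_curve_has_zero_ratio(self):
        s = segment_signature(curve("C5-C6", [70.0, 70.0, 70.0]))
        assert s.delta_s == 0.0
        assert s.ratio == 0.0

    def test_scale_invariance(self):
        a = segment_signature(curve("C5-C6", [100.0, 80.0, 60.0]))
        b = segment_signature(curve("C5-C6", [200.0, 160.0, 120.0]))
        assert a.ratio == pytest.approx(b.ratio)

    def test_zero_area_curve_flagged(self):
        s = segment_signature(curve("C5-C6", [0.0, 0.0]))
        assert s.zero_motion and s.ratio == 0.0


class TestSpineSignature:
    def test_series_ordered_cranial_to_caudal(self):
        sig = cervical_signature([0.3, 0.35, 0.4, 0.1, 0.3])
        assert sig.levels == CERVICAL_LEVELS
        assert np.allclose(sig.ratios, [0.3, 0.35, 0.4, 0.1, 0.3])

    def test_shuffled_input_gives_identical_series(self):
        curves = {lv: curve(lv, [10.0, 8.0]) for lv in CERVICAL_LEVELS}
        a = spine_signature(curves, "cervical")
        b = spine_signature({lv: curves[lv] for lv in reversed(CERVICAL_LEVELS)}, "cervical")
        assert a == b

    def test_duplicate_level_rejected(self):
        curves = [curve("C5-C6", [10.0, 8.0]), curve("C5-C6", [9.0, 8.0])]
        with pytest.raises(DuplicateLevelError):
            spine_signature(curves, "cervical")

    def test_missing_level_rejected(self):
        curves = {lv: curve(lv, [10.0, 8.0]) for lv in CERVICAL_LEVELS[:-1]}
        with pytest.raises(IncompleteSectionError):
            spine_signature(curves, "cervical")


class TestSignatureDistance:
    def test_identity_and_single_coordinate(self):
        a = cervical_signature([0.3, 0.35, 0.4, 0.1, 0.3])
        b = cervical_signature([0.3, 0.35, 0.4, 0.4, 0.3])
        assert signature_distance(a, a) == 0.0
        assert signature_distance(a, b) == pytest.approx(0.3)
        assert signature_distance(a, b) == signature_distance(b, a)

    def test_sections_must_match(self):
        a = cervical_signature([0.3] * 5)
        b = SpineSignature("lumbar", a.signatures)
        with pytest.raises(IncompatibleSignatureError):
            signature_distance(a, b)


class TestBayesError:
    def test_two_gaussians_mean_gap_two_sigma_matches_phi(self):
        err, se = gaussian_bayes_error(
            np.array([[0.0], [2.0]]), np.array([1.0]), n_draws=100_000, rng=0
        )
        assert err == pytest.approx(norm.cdf(-1.0), abs=0.01)
        assert se < 0.01

    def test_identical_class_distributions_give_chance_error(self):
        sigs = {
            "a": (cervical_signature([0.4] * 5), cervical_signature([0.42] * 5)),
            "b": (cervical_signature([0.4] * 5), cervical_signature([0.42] * 5)),
        }
        report = bayes_error_rate(sigs, n_draws=20_000, rng=0)
        assert report.bayes_error == pytest.approx(0.5, abs=0.02)

    def test_widely_separated_subjects_are_identifiable(self, rng):
        sigs = {}
        for i in range(5):
            base = 0.1 + 0.15 * i  # gaps of 0.15 >> within-subject sd of 0.002
            a = np.clip(base + rng.normal(0, 0.002, 5), 0, 1)
            b = np.clip(base + rng.normal(0, 0.002, 5), 0, 1)
            sigs[f"s{i}"] = (cervical_signature(a), cervical_signature(b))
        report = bayes_error_rate(sigs, n_draws=20_000, rng=1)
        assert report.bayes_error < 0.01
        assert report.nn_error == 0.0
        # Cover-Hart direction at the estimate level
        assert report.nn_error >= report.bayes_error - 3 * report.mc_se

    def test_single_subject_rejected(self):
        sigs = {"a": (cervical_signature([0.4] * 5), cervical_signature([0.4] * 5))}
        with pytest.raises(InsufficientCohortError):
            bayes_error_rate(sigs, n_draws=100)


class TestWorstBestDetection:
    def test_identical_patient_ties_all_levels(self, reference):
        result = detect_worst_segment(dict(reference.curves), reference)
        assert result.tie
        assert max(result.deviations.values()) == 0.0
        # caudal tie-break
        assert result.level == CERVICAL_LEVELS[-1]

    def test_deviation_invariant_to_uniform_rescaling(self, reference):
        patient = {
            lv: MotionCurve(lv, c.fraction, 250.0 * c.area)
            for lv, c in reference.curves.items()
        }
        result = detect_worst_segment(patient, reference)
        assert max(result.deviations.values()) < 1e-9

    def test_missing_reference_level_rejected(self, reference):
        patient = {"T1-T2": curve("T1-T2", [10.0, 8.0])}
        with pytest.raises(ReferenceGapError):
            detect_worst_segment(patient, reference)

    def test_dominant_level_wins_best(self, reference):
        patient = dict(reference.curves)
        heights = {lv: 0.6 * reference.neutral_heights[lv] for lv in patient}
        heights["C3-C4"] = reference.neutral_heights["C3-C4"]
        best = detect_best_segment(patient, heights, reference)
        assert best.level == "C3-C4"

    def test_height_only_weights_ignore_curves(self, reference):
        patient = dict(reference.curves)
        heights = {lv: reference.neutral_heights[lv] for lv in patient}
        heights["C6-C7"] *= 1.5
        best = detect_best_segment(patient, heights, reference, weights=(1.0, 0.0))
        assert best.level == "C6-C7"

    def test_all_levels_excluded_rejected(self, reference):
        patient = dict(reference.curves)
        heights = {lv: reference.neutral_heights[lv] for lv in patient}
        with pytest.raises(NoCandidateError):
            detect_best_segment(patient, heights, reference, exclude=set(patient))


class TestDiscHeightEstimate:
    def test_minimum_based_estimate_without_reference(self):
        # apex height 6 mm at the resting pose, baseline 30 -> S_min = 90
        c = curve("C5-C6", [90.0, 110.0, 130.0])
        assert estimate_disc_height(c, 30.0) == pytest.approx(6.0)

    def test_rank_regression_recovers_height_with_reference(self, reference):
        ref = reference.curves["C4-C5"]
        sigma = (ref.area - ref.area.min()) / (ref.area.max() - ref.area.min())
        b, h, amp = 15.9, 5.83, 4.2
        patient = MotionCurve("C4-C5", ref.fraction, 0.5 * b * (h + amp * sigma))
        assert estimate_disc_height(patient, b, ref) == pytest.approx(h, abs=1e-9)
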