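"""SUL arithmetic, lesion segmentation, SUL_peak, measurability and
response classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from lbmct.ct_io import ImageVolume
from lbmct.exceptions import ConfigError, ContentError, DomainError, GeometryError
from lbmct.percist import (
    BackgroundStats,
    LesionMeasurement,
    ResponseClass,
    adaptive_threshold_segment,
    classify_change,
    classify_response,
    is_measurable,
    liver_background,
    percent_change,
    rescale_sul_peak,
    select_target_lesion,
    sphere_kernel,
    sul_peak,
    suv_to_sul,
)


def _pet(vox, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(vox, dtype=float), spacing, modality="PET")


class TestSulArithmetic:
    def test_identity_when_lbm_equals_weight(self):
        assert suv_to_sul(5.0, 60.0, 60.0) == 5.0

    def test_ratio(self):
        assert suv_to_sul(5.0, 42.0, 60.0) == pytest.approx(3.5)

    @pytest.mark.parametrize("args", [(5.0, 42.0, 0.0), (0.0, 42.0, 60.0), (5.0, -1.0, 60.0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(DomainError):
            suv_to_sul(*args)

    def test_rescale_with_cohort_mean_lbms(self):
        assert rescale_sul_peak(4.0, 47.01, 42.26) == pytest.approx(3.5958, abs=1e-4)

    def test_rescale_identity(self):
        assert rescale_sul_peak(4.0, 45.0, 45.0) == 4.0

    @given(st.floats(0.5, 20), st.floats(30, 70), st.floats(30, 70))
    @settings(max_examples=50, deadline=None)
    def test_rescale_round_trip(self, sul, a, b):
        there = rescale_sul_peak(sul, a, b)
        back = rescale_sul_peak(there, b, a)
        assert back == pytest.approx(sul, rel=1e-12)


class TestAdaptiveSegmentation:
    def test_two_level_image_converges_to_lesion(self):
        vox = np.ones((16, 16, 16))
        lesion = np.zeros((16, 16, 16), bool)
        lesion[5:11, 5:11, 5:11] = True
        vox[lesion] = 10.0
        seed = ndimage.binary_dilation(lesion, iterations=2)
        res = adaptive_threshold_segment(_pet(vox), seed)
        np.testing.assert_array_equal(res.mask, lesion)
        assert res.threshold == pytest.approx(10.0)
        assert res.converged

    def test_homogeneous_image_fixpoint(self):
        vox = np.full((8, 8, 8), 3.0)
        seed = np.zeros((8, 8, 8), bool)
        seed[2:6, 2:6, 2:6] = True
        res = adaptive_threshold_segment(_pet(vox), seed)
        assert res.threshold == pytest.approx(3.0)
        assert res.mask.all()  # entire (fully connected) image is >= 3.0

    def test_final_threshold_is_a_fixpoint_on_ramp(self):
        """On a linear-ramp lesion, the converged mask must satisfy the
        fixpoint equation, and must appear in a brute-force enumeration of
        all candidate-threshold fixpoints."""
        w = 0.5
        vox = np.zeros((12, 12, 12))
        zz, yy, xx = np.indices((12, 12, 12))
        lesion = (zz - 6) ** 2 + (yy - 6) ** 2 + (xx - 6) ** 2 <= 16
        vox[lesion] = 2.0 + 0.5 * zz[lesion]  # linear SUV ramp
        pet = _pet(vox)
        seed = lesion.copy()
        res = adaptive_threshold_segment(pet, seed, weight_factor=w, tol=1e-9)

        peak = np.unravel_index(np.argmax(np.where(seed, vox, -np.inf)), vox.shape)
        struct = ndimage.generate_binary_structure(3, 3)

        def mask_at(t):
            cand = vox >= t
            labels, _ = ndimage.label(cand, structure=struct)
            return labels == labels[peak]

        def g(mask):
            inside = vox[mask]
            return w * inside.max() + (1 - w) * inside.mean()

        # implementation's converged threshold satisfies the fixpoint equation
        assert abs(g(res.mask) - res.threshold) < 1e-6
        # enumerate every distinct voxel value as candidate threshold
        fixpoints = []
        for t in np.unique(vox[vox > 0]):
            m = mask_at(t)
            if np.array_equal(mask_at(g(m)), m):
                fixpoints.append(m)
        assert any(np.array_equal(res.mask, m) for m in fixpoints)

    def test_threshold_sequence_recorded(self):
        vox = np.ones((10, 10, 10))
        vox[4:7, 4:7, 4:7] = 8.0
        seed = np.ones((10, 10, 10), bool)
        res = adaptive_threshold_segment(_pet(vox), seed)
        assert len(res.thresholds) == res.n_iter >= 2
        assert res.thresholds[-1] == res.threshold

    def test_bad_weight_factor(self):
        with pytest.raises(DomainError):
            adaptive_threshold_segment(_pet(np.ones((4, 4, 4))), np.ones((4, 4, 4), bool), 1.5)


class TestSulPeak:
    def test_uniform_lesion(self):
        vox = np.ones((30, 30, 30))
        lesion = np.zeros((30, 30, 30), bool)
        lesion[5:25, 5:25, 5:25] = True
        vox[lesion] = 8.0
        assert sul_peak(_pet(vox, (3, 3, 3)), lesion) == pytest.approx(8.0)

    def test_single_hot_voxel_mean_over_sphere(self):
        vox = np.zeros((21, 21, 21))
        vox[10, 10, 10] = 10.0
        lesion = vox > 0
        n = sphere_kernel((1.0, 1.0, 1.0), 12.0).sum()
        assert sul_peak(_pet(vox), lesion) == pytest.approx(10.0 / n)

    def test_never_exceeds_max(self):
        rng = np.random.default_rng(3)
        vox = rng.uniform(0, 10, (15, 15, 15))
        lesion = np.zeros((15, 15, 15), bool)
        lesion[5:10, 5:10, 5:10] = True
        assert sul_peak(_pet(vox, (2, 2, 2)), lesion) <= vox.max()

    def test_sphere_larger_than_image(self):
        with pytest.raises(GeometryError):
            sul_peak(_pet(np.ones((4, 4, 4))), np.ones((4, 4, 4), bool), sphere_diameter_mm=50)

    def test_invariant_to_far_voxel_permutation(self):
        rng = np.random.default_rng(5)
        vox = rng.uniform(0, 2, (30, 16, 16))
        lesion = np.zeros((30, 16, 16), bool)
        lesion[3:7, 6:10, 6:10] = True
        vox[lesion] += 8.0
        pet = _pet(vox)
        before = sul_peak(pet, lesion)
        far = vox.copy()
        far[20:] = rng.permutation(far[20:].ravel()).reshape(far[20:].shape)
        assert sul_peak(_pet(far), lesion) == pytest.approx(before, rel=1e-12)


class TestLiverBackground:
    def test_uniform_liver(self):
        pet = _pet(np.full((20, 20, 20), 2.0), (3, 3, 3))
        bg = liver_background(pet, (30, 30, 30), 30.0)
        assert bg.liver_sul_mean == pytest.approx(2.0)
        assert bg.liver_sul_sd == 0.0

    def test_two_value_sphere_population_sd(self):
        vox = np.full((21, 21, 21), 1.0)
        vox[:, :, 11:] = 3.0  # half/half split through the ROI center plane
        pet = _pet(vox, (1, 1, 1))
        bg = liver_background(pet, (10, 10, 10.5), 8.0, ddof=0)
        assert bg.liver_sul_mean == pytest.approx(2.0)
        assert bg.liver_sul_sd == pytest.approx(1.0)

    def test_out_of_bounds_center(self):
        pet = _pet(np.ones((10, 10, 10)))
        with pytest.raises(GeometryError):
            liver_background(pet, (100, 100, 100), 30.0)


class TestMeasurability:
    def test_liver_rule_threshold(self):
        bg = BackgroundStats(liver_sul_mean=2.0, liver_sul_sd=0.3)
        res = is_measurable(3.7, bg)
        assert res.threshold == pytest.approx(3.6)
        assert res.measurable

    def test_below_liver_threshold(self):
        bg = BackgroundStats(liver_sul_mean=2.0, liver_sul_sd=0.3)
        assert not is_measurable(3.5, bg).measurable

    def test_blood_pool_rule(self):
        bg = BackgroundStats(liver_sul_mean=5.0, liver_sul_sd=1.0, blood_sul_mean=1.5)
        res = is_measurable(3.01, bg, use_blood_pool=True)
        assert res.threshold == pytest.approx(3.0)
        assert res.measurable
        assert not is_measurable(3.0, bg, use_blood_pool=True).measurable  # strict >

    def test_missing_blood_pool_stats(self):
        bg = BackgroundStats(liver_sul_mean=2.0, liver_sul_sd=0.3)
        with pytest.raises(ConfigError):
            is_measurable(3.7, bg, use_blood_pool=True)

    def test_strict_parse_variant(self):
        bg = BackgroundStats(liver_sul_mean=2.0, liver_sul_sd=0.3)
        assert is_measurable(0, bg, strict_parse=True).threshold == pytest.approx(1.5 * 2.6)


class TestClassification:
    @pytest.mark.parametrize(
        "base,follow,expected",
        [
            (5.0, 3.5, ResponseClass.PMR),   # exactly -30%, abs 1.5
            (2.0, 1.4, ResponseClass.SMD),   # -30% but abs 0.6 < 0.8 gate
            (5.0, 6.4, ResponseClass.SMD),   # +28%
            (5.0, 6.5, ResponseClass.PMD),   # exactly +30%, abs 1.5
            (5.0, 5.0, ResponseClass.SMD),
            (5.0, 3.5005, ResponseClass.SMD),  # -29.99%
            (5.0, 6.4995, ResponseClass.SMD),  # +29.99%
        ],
    )
    def test_boundary_suite(self, base, follow, expected):
        assert classify_change(base, follow).response == expected

    @pytest.mark.parametrize("base,follow,expected", [(5.0, 3.5, -30.0), (5.0, 5.0, 0.0), (5.0, 6.5, 30.0)])
    def test_percent_change(self, base, follow, expected):
        assert percent_change(base, follow) == pytest.approx(expected)

    def test_percent_change_requires_positive_baseline(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 3.0)

    def test_classify_response_from_measurements(self):
        b = LesionMeasurement(5.0, "baseline", "L1")
        f = LesionMeasurement(3.5, "followup", "L1")
        res = classify_response(b, f, algorithm="PE")
        assert res.response == ResponseClass.PMR
        assert res.algorithm == "PE"

    @given(st.floats(1, 20), st.floats(0.1, 3))
    @settings(max_examples=60, deadline=None)
    def test_ordinal_coherence_in_followup(self, base, step):
        """Raising the follow-up SUL never moves the class toward PMR."""
        lows = classify_change(base, base * 0.5).response
        mids = classify_change(base, base * 0.5 + step).response
        assert mids <= lows  # IntEnum ordering PMD=1 < SMD=2 < PMR=3

    def test_classes_identical_when_lbm_unchanged(self):
        """The core mechanism: a common LBM ratio at both timepoints cancels
        in the percent change, so PE- and LC-based classes agree; a ratio
        that changes between timepoints does not cancel."""
        base_pe, fu_pe = 6.0, 4.3
        ratio = 0.9
        same = (
            percent_change(base_pe, fu_pe),
            percent_change(base_pe * ratio, fu_pe * ratio),
        )
        assert same[0] == pytest.approx(same[1], rel=1e-12)
        changed = percent_change(base_pe * ratio, fu_pe * 0.95 * ratio)
        assert changed != pytest.approx(same[0], rel=1e-6)


class TestTargetSelection:
    def test_hottest_lesion(self):
        lesions = [
            LesionMeasurement(4.2, "baseline", "a"),
            LesionMeasurement(7.1, "baseline", "b"),
            LesionMeasurement(3.3, "baseline", "c"),
        ]
        assert select_target_lesion(lesions).lesion_id == "b"

    def test_single_lesion(self):
        only = LesionMeasurement(2.2, "followup", "x")
        assert select_target_lesion([only]) is only

    def test_tie_breaks_lexicographically(self):
        lesions = [
            LesionMeasurement(5.0, "baseline", "zeta"),
            LesionMeasurement(5.0, "baseline", "alpha"),
        ]
        assert select_target_lesion(lesions).lesion_id == "alpha"

    def test_empty_list(self):
        with pytest.raises(ContentError):
            select_target_lesion([])

    def test_mixed_timepoints_rejected(self):
        with pytest.raises(DomainError):
            select_target_lesion(
                [LesionMeasurement(1, "baseline", "a"), LesionMeasurement(2, "followup", "b")]
            )
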