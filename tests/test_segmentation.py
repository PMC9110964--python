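import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from renalseg.config import PipelineConfig, SegmentationConfig
from renalseg.core import AlignmentError, DomainError
from renalseg.phantom import PhantomSpec, generate_phantom
from renalseg.preprocess import band_shift, median_denoise
from renalseg.segmentation import (
    binarize,
    compute_histogram,
    dilate,
    intersect_masks,
    particle_removal,
    run_full_pipeline,
    segment_calculus,
    segment_collecting_system,
    segment_skeleton,
    subtract_masks,
)

from .conftest import make_mask, make_volume
from . import oracles


class TestHistogram:
    def test_constant_volume_single_bin(self):
        h = compute_histogram(make_volume(np.full((4, 4, 4), 100.0)))
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 64

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        vol = make_volume(rng.uniform(0, 255, (5, 6, 7)))
        assert compute_histogram(vol).counts.sum() == 5 * 6 * 7

    def test_two_value_volume_equal_bins(self):
        arr = np.empty((2, 4, 4))
        arr[0], arr[1] = 50.0, 200.0
        h = compute_histogram(make_volume(arr), n_bins=256)
        nonzero = h.counts[h.counts > 0]
        assert len(nonzero) == 2 and nonzero[0] == nonzero[1] == 16

    def test_requires_shifted_domain(self):
        with pytest.raises(DomainError):
            compute_histogram(make_volume(np.zeros((2, 2, 2)), domain="hounsfield"))

    def test_bad_bins(self):
        with pytest.raises(ValueError):
            compute_histogram(make_volume(np.zeros((2, 2, 2))), n_bins=0)


class TestBinarize:
    def test_inclusive_bounds(self):
        vol = make_volume(np.array([[[116.0, 117.0, 180.0, 181.0]]]))
        mask = binarize(vol, 117, 180)
        np.testing.assert_array_equal(mask.bits[0, 0], [False, True, True, False])

    def test_full_range_all_true(self):
        vol = make_volume(np.random.default_rng(0).uniform(0, 255, (3, 3, 3)))
        assert binarize(vol, 0, 255).bits.all()

    def test_equal_thresholds(self):
        vol = make_volume(np.array([[[1.0, 2.0, 2.0, 3.0]]]))
        assert binarize(vol, 2, 2).voxel_count == 2

    def test_lower_above_upper_rejected(self):
        with pytest.raises(ValueError):
            binarize(make_volume(np.zeros((2, 2, 2))), 10, 5)

    @given(
        hnp.arrays(float, (4, 4, 4), elements=st.floats(0, 255)),
        st.floats(0, 255), st.floats(0, 255), st.floats(0, 30), st.floats(0, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_band_width(self, arr, lo, hi, widen_lo, widen_hi):
        lo, hi = min(lo, hi), max(lo, hi)
        vol = make_volume(arr)
        narrow = binarize(vol, lo, hi).bits
        wide = binarize(vol, max(lo - widen_lo, 0), min(hi + widen_hi, 255)).bits
        assert not np.any(narrow & ~wide)


class TestMorphology:
    def test_isolated_voxel_removed(self):
        bits = np.zeros((7, 7, 7), bool)
        bits[3, 3, 3] = True
        assert particle_removal(make_mask(bits), 3).voxel_count == 0

    def test_solid_block_preserved(self):
        bits = np.zeros((9, 9, 9), bool)
        bits[2:7, 2:7, 2:7] = True
        out = particle_removal(make_mask(bits), 3)
        np.testing.assert_array_equal(out.bits, bits)

    def test_cube_dim_one_is_identity(self):
        rng = np.random.default_rng(8)
        bits = rng.random((6, 6, 6)) < 0.4
        np.testing.assert_array_equal(particle_removal(make_mask(bits), 1).bits, bits)
        np.testing.assert_array_equal(dilate(make_mask(bits), 1).bits, bits)

    def test_dilate_center_voxel(self):
        bits = np.zeros((5, 5, 5), bool)
        bits[2, 2, 2] = True
        out = dilate(make_mask(bits), 3, 1)
        expected = np.zeros((5, 5, 5), bool)
        expected[1:4, 1:4, 1:4] = True
        np.testing.assert_array_equal(out.bits, expected)

    def test_dilate_empty(self):
        out = dilate(make_mask(np.zeros((4, 4, 4), bool)), 3)
        assert out.voxel_count == 0

    @given(hnp.arrays(bool, (5, 5, 5)), st.integers(1, 3), st.integers(1, 2))
    @settings(max_examples=50, deadline=None)
    def test_dilation_extensive(self, bits, dim, iterations):
        out = dilate(make_mask(bits), dim, iterations)
        assert not np.any(bits & ~out.bits)

    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_matches_pure_loop_oracle(self, dim):
        rng = np.random.default_rng(dim)
        for _ in range(3):
            bits = rng.random((5, 5, 5)) < 0.5
            mask = make_mask(bits)
            np.testing.assert_array_equal(
                dilate(mask, dim).bits, oracles.loop_dilate(bits, dim)
            )
            opened = oracles.loop_dilate(oracles.loop_erode(bits, dim), dim)
            closed = oracles.loop_erode(oracles.loop_dilate(opened, dim), dim)
            np.testing.assert_array_equal(particle_removal(mask, dim).bits, closed)

    def test_loop_and_shift_oracles_agree(self):
        rng = np.random.default_rng(9)
        for dim in (1, 2, 3):
            bits = rng.random((5, 5, 5)) < 0.5
            np.testing.assert_array_equal(
                oracles.loop_erode(bits, dim), oracles.shift_erode(bits, dim)
            )
            np.testing.assert_array_equal(
                oracles.loop_dilate(bits, dim), oracles.shift_dilate(bits, dim)
            )


class TestMaskAlgebra:
    def _pair(self):
        rng = np.random.default_rng(4)
        a = make_mask(rng.random((4, 4, 4)) < 0.5)
        b = make_mask(rng.random((4, 4, 4)) < 0.5)
        return a, b

    def test_intersection_idempotent(self):
        a, _ = self._pair()
        np.testing.assert_array_equal(intersect_masks(a, a).bits, a.bits)

    def test_intersection_with_empty(self):
        a, _ = self._pair()
        empty = make_mask(np.zeros((4, 4, 4), bool))
        assert intersect_masks(a, empty).voxel_count == 0

    def test_disjoint_singletons(self):
        a = np.zeros((3, 3, 3), bool); a[0, 0, 0] = True
        b = np.zeros((3, 3, 3), bool); b[2, 2, 2] = True
        assert intersect_masks(make_mask(a), make_mask(b)).voxel_count == 0

    def test_subtract_self_empty(self):
        a, _ = self._pair()
        assert subtract_masks(a, a).voxel_count == 0

    def test_subtract_empty_identity(self):
        a, _ = self._pair()
        empty = make_mask(np.zeros((4, 4, 4), bool))
        np.testing.assert_array_equal(subtract_masks(a, empty).bits, a.bits)

    @given(hnp.arrays(bool, (4, 4, 4)), hnp.arrays(bool, (4, 4, 4)))
    @settings(max_examples=50, deadline=None)
    def test_subtraction_disjoint_from_subtrahend(self, abits, bbits):
        a, b = make_mask(abits), make_mask(bbits)
        diff = subtract_masks(a, b)
        assert intersect_masks(diff, b).voxel_count == 0

    def test_geometry_mismatch_rejected(self):
        a = make_mask(np.zeros((3, 3, 3), bool))
        b = make_mask(np.zeros((3, 3, 3), bool), spacing=(2, 2, 2))
        with pytest.raises(AlignmentError):
            intersect_masks(a, b)
        with pytest.raises(AlignmentError):
            subtract_masks(a, b)
        c = make_mask(np.zeros((4, 3, 3), bool))
        with pytest.raises(AlignmentError):
            intersect_masks(a, c)


def _prep(volume):
    return median_denoise(band_shift(volume), 1)


class TestSkeleton:
    def test_phantom_recall_and_specificity(self, default_phantom, pipeline_result):
        _, _, truth = default_phantom
        skeleton = pipeline_result.skeleton.bits
        bone = truth.mask("bone")
        recall = (skeleton & bone).sum() / bone.sum()
        assert recall >= 0.90
        assert (skeleton & truth.mask("collecting_system")).sum() == 0

    def test_no_bone_gives_empty_skeleton(self):
        spec = dataclasses.replace(PhantomSpec(seed=3).scaled(1 / 3), bones=())
        native, delayed, _ = generate_phantom(spec)
        skeleton, _ = segment_skeleton(_prep(native), _prep(delayed))
        assert skeleton.voxel_count == 0

    def test_all_bone_matches_brute_force_pipeline(self):
        # every voxel inside both bands: pipeline reduces to pure morphology
        native = make_volume(np.full((8, 8, 8), 160.0))
        delayed = make_volume(np.full((8, 8, 8), 160.0))
        skeleton, inter = segment_skeleton(native, delayed)
        ones = np.ones((8, 8, 8), bool)
        step3 = oracles.shift_dilate(oracles.shift_particle_removal(ones, 3), 3)
        step5 = oracles.shift_particle_removal(ones, 3)
        np.testing.assert_array_equal(skeleton.bits, step3 & step5)

    def test_intermediates_complete(self, pipeline_result):
        inter = pipeline_result.intermediates
        assert set(inter) == {f"step{i}" for i in range(1, 7)}
        np.testing.assert_array_equal(
            pipeline_result.skeleton.bits, inter["step6"].bits
        )


class TestCollectingSystem:
    def test_phantom_dice(self, default_phantom, pipeline_result):
        _, _, truth = default_phantom
        cs = pipeline_result.collecting_system.bits
        truth_cs = truth.mask("collecting_system") | truth.mask("stone")
        dice = 2 * (cs & truth_cs).sum() / (cs.sum() + truth_cs.sum())
        assert dice >= 0.80

    def test_equal_steps_give_empty(self):
        rng = np.random.default_rng(6)
        m = make_mask(rng.random((4, 4, 4)) < 0.5)
        assert segment_collecting_system(m, m).voxel_count == 0

    def test_disjoint_from_skeleton(self, pipeline_result):
        cs = pipeline_result.collecting_system
        overlap = intersect_masks(cs, pipeline_result.skeleton)
        assert overlap.voxel_count == 0


class TestCalculus:
    def test_phantom_recovery(self, default_phantom, pipeline_result):
        _, _, truth = default_phantom
        count = pipeline_result.calculus.voxel_count
        analytic_count = truth.stone_volume_mm3 / truth.geometry.voxel_volume_mm3
        assert abs(count - analytic_count) / analytic_count <= 0.10

    def test_below_band_empty(self):
        vol = make_volume(np.full((5, 5, 5), 200.0))
        assert segment_calculus(vol).voxel_count == 0

    def test_two_stones_two_components(self):
        arr = np.full((12, 12, 12), 111.0)
        arr[2:5, 4:8, 4:8] = 252.0
        arr[8:11, 4:8, 4:8] = 252.0
        mask = segment_calculus(make_volume(arr))
        _, n = ndimage.label(mask.bits, structure=np.ones((3, 3, 3)))
        assert n == 2


class TestFullPipeline:
    def test_all_masks_non_empty(self, pipeline_result):
        assert pipeline_result.skeleton.voxel_count > 0
        assert pipeline_result.collecting_system.voxel_count > 0
        assert pipeline_result.calculus.voxel_count > 0

    def test_requires_hounsfield_inputs(self, small_phantom):
        native, delayed, _ = small_phantom
        with pytest.raises(DomainError, match="Hounsfield"):
            run_full_pipeline(band_shift(native), delayed)

    def test_no_contrast_means_no_collecting_system_coverage(
        self, clean_small_phantom
    ):
        native, _, truth = clean_small_phantom
        # delayed identical to native: nothing is contrast-enhanced
        fake_delayed = native.with_voxels(native.voxels.copy(), phase="delayed")
        result = run_full_pipeline(native, fake_delayed, skip_registration=True)
        covered = result.collecting_system.bits & truth.mask("collecting_system")
        assert covered.sum() == 0

    def test_stage_log_records_stages(self, pipeline_result):
        stages = [e["stage"] for e in pipeline_result.stage_log]
        assert stages == [
            "band_shift", "median_denoise", "coregister",
            "segment_skeleton", "segment_collecting_system", "segment_calculus",
        ]

    def test_registration_recovers_phantom_misalignment(
        self, default_phantom, pipeline_result
    ):
        _, _, truth = default_phantom
        recovered = pipeline_result.registration.transform
        rot_err = np.rad2deg(recovered.rotation - truth.misalignment.rotation)
        assert np.all(np.abs(rot_err) < 0.5)
        # both transforms share the grid-centre rotation centre
        trans_err = recovered.translation - truth.misalignment.translation
        assert np.all(np.abs(trans_err) < 0.5)
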