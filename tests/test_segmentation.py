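"""Blob-detector unit tests: contrast stretch, separable Gaussian blur
against a direct 2-D convolution oracle, DOG behavior, thresholding,
connected-component labeling against a flood-fill oracle, and the full
detector on synthetic ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from caflux.segmentation import (
    ROISet,
    SegmentationParams,
    detect_rois,
    dog_filter,
    gaussian_blur,
    gaussian_kernel_1d,
    label_components,
    merge_manual_rois,
    stretch_contrast,
    threshold_binary,
)
from caflux.synthetic import SyntheticSpec, generate_movie
from caflux.evaluation import match_rois

from conftest import direct_gaussian_blur_2d, flood_fill_labels, partition_of, roiset_from_grid


class TestStretchContrast:
    def test_direct_formula(self):
        out = stretch_contrast(np.array([[2.0, 4.0], [6.0, 10.0]]))
        np.testing.assert_allclose(out, [[0.0, 0.25], [0.5, 1.0]])

    def test_identity_on_unit_range(self):
        frame = np.array([[0.0, 0.3], [0.7, 1.0]])
        np.testing.assert_allclose(stretch_contrast(frame), frame)

    def test_constant_frame_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = stretch_contrast(np.full((4, 4), 7.0))
        assert (out == 0).all()

    @settings(derandomize=True, max_examples=30)
    @given(
        hnp.arrays(
            float,
            (6, 6),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_bounded_and_idempotent(self, frame):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = stretch_contrast(frame)
            assert out.min() >= 0.0 and out.max() <= 1.0
            np.testing.assert_allclose(stretch_contrast(out), out, atol=1e-12)


class TestGaussianBlur:
    def test_kernel_normalized_and_symmetric(self):
        w = gaussian_kernel_1d(2.0)
        assert len(w) == 2 * 6 + 1
        np.testing.assert_allclose(w.sum(), 1.0)
        np.testing.assert_allclose(w, w[::-1])

    def test_constant_frame_preserved(self):
        frame = np.full((16, 16), 3.7)
        np.testing.assert_allclose(gaussian_blur(frame, 2.5), frame, atol=1e-12)

    def test_impulse_response_is_kernel_outer_product(self):
        frame = np.zeros((33, 33))
        frame[16, 16] = 1.0
        w = gaussian_kernel_1d(2.0)
        expected = np.outer(w, w)
        out = gaussian_blur(frame, 2.0)
        np.testing.assert_allclose(out[10:23, 10:23], expected, atol=1e-12)

    @pytest.mark.parametrize("sigma", [1.0, 2.0, 5.0])
    def test_separable_equals_direct_2d_convolution(self, sigma, rng):
        frame = rng.random((64, 64))
        assert np.abs(gaussian_blur(frame, sigma) - direct_gaussian_blur_2d(frame, sigma)).max() <= 1e-9

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((4, 4)), 0.0)


class TestDogFilter:
    def test_equal_sigmas_cancel(self, rng):
        frame = rng.random((32, 32))
        assert np.abs(dog_filter(frame, 2.0, 2.0)).max() == 0.0

    def test_linearity(self, rng):
        f, g = rng.random((24, 24)), rng.random((24, 24))
        lhs = dog_filter(f + g, 2.0, 5.0)
        rhs = dog_filter(f, 2.0, 5.0) + dog_filter(g, 2.0, 5.0)
        assert np.abs(lhs - rhs).max() <= 1e-9

    def test_bright_disk_responds_positively_at_center(self):
        frame = np.zeros((41, 41))
        rr, cc = np.ogrid[:41, :41]
        frame[(rr - 20) ** 2 + (cc - 20) ** 2 <= 16] = 1.0
        out = dog_filter(frame, 2.0, 6.0)
        assert out[20, 20] > 0.0


class TestThreshold:
    def test_empty_and_full(self):
        assert not threshold_binary(np.zeros((3, 3)), 0.1).any()
        assert threshold_binary(np.ones((3, 3)), 0.5).all()

    def test_boundary_is_strict(self):
        assert not threshold_binary(np.array([[0.5]]), 0.5).any()


class TestLabelComponents:
    def test_two_separated_squares(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0:3, 0:3] = True
        mask[5:8, 5:8] = True
        assert len(label_components(mask)) == 2

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, connectivity=4)) == 2
        assert len(label_components(mask, connectivity=8)) == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(25):
            mask = rng.random((50, 50)) < 0.45
            ours = label_components(mask, connectivity=connectivity, min_size_px=1)
            ours_partition = {r.pixel_set for r in ours}
            assert ours_partition == partition_of(flood_fill_labels(mask, connectivity))

    def test_min_size_filter_drops_small_clusters(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 0] = True  # area 1
        mask[3:5, 3:5] = True  # area 4
        rois = label_components(mask, min_size_px=4)
        assert len(rois) == 1 and rois.ids == [1]

    def test_partition_covers_mask(self, rng):
        mask = rng.random((30, 30)) < 0.4
        rois = label_components(mask, min_size_px=1)
        covered = set()
        for r in rois:
            assert covered.isdisjoint(r.pixel_set)
            covered |= r.pixel_set
        assert covered == set(map(tuple, np.argwhere(mask).tolist()))


class TestDetectRois:
    def test_blank_frame_gives_no_rois(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rois = detect_rois(np.zeros((1, 32, 32)), 0, SegmentationParams())
        assert len(rois) == 0

    def test_recovers_synthetic_blobs(self):
        spec = SyntheticSpec(
            seed=7, n_cells=20, n_frames=1, spike_rate=0.0, blob_sigma_px=3.0,
            baseline_range=(50.0, 50.0), noise_sigma=5.0,
        )
        stack, truth = generate_movie(spec)
        rois = detect_rois(stack, 0, SegmentationParams(th=0.1))
        result = match_rois(rois, truth.rois)
        assert result.counts.TP >= 19
        assert result.counts.FP == 0
        for did, (kind, tid) in result.assignment.items():
            if kind == "tp":
                d, t = rois[did].centroid, truth.rois[tid].centroid
                assert np.hypot(d[0] - t[0], d[1] - t[1]) <= 3.0

    def test_roi_count_monotone_in_threshold(self):
        spec = SyntheticSpec(seed=7, n_cells=10, n_frames=1, spike_rate=0.0,
                             baseline_range=(50.0, 50.0), noise_sigma=5.0)
        stack, _ = generate_movie(spec)
        counts = [
            len(detect_rois(stack, 0, SegmentationParams(th=th)))
            for th in (0.05, 0.1, 0.2, 0.5, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_invariant_to_positive_scaling(self):
        spec = SyntheticSpec(seed=11, n_cells=8, n_frames=1, spike_rate=0.0,
                             baseline_range=(50.0, 50.0), noise_sigma=5.0)
        stack, _ = generate_movie(spec)
        params = SegmentationParams(th=0.1)
        base = detect_rois(stack.frames, 0, params)
        scaled = detect_rois(stack.frames * 37.5, 0, params)
        assert {r.pixel_set for r in base} == {r.pixel_set for r in scaled}

    def test_bad_reference_frame_index(self):
        with pytest.raises(IndexError):
            detect_rois(np.zeros((2, 8, 8)), 5, SegmentationParams())


class TestMergeManualRois:
    def test_remove_only_roi(self):
        rois = roiset_from_grid([[1, 1], [0, 0]])
        assert len(merge_manual_rois(rois, remove=[1])) == 0

    def test_remove_unknown_id_raises(self):
        rois = roiset_from_grid([[1, 1], [0, 0]])
        with pytest.raises(KeyError):
            merge_manual_rois(rois, remove=[9])

    def test_add_to_empty_set(self):
        empty = ROISet([], shape=(3, 3))
        add = np.array([[0, 0, 0], [0, 5, 5], [0, 0, 0]])
        merged = merge_manual_rois(empty, add=add)
        assert len(merged) == 1 and merged[1].area_px == 2

    def test_added_cluster_shrinks_overlapping_auto_roi(self):
        auto = roiset_from_grid([[1, 1, 1, 0]])
        add = np.array([[0, 0, 2, 2]])
        merged = merge_manual_rois(auto, add=add)
        by_area = sorted((r.area_px, r.pixel_set) for r in merged)
        assert len(merged) == 2
        assert by_area[0] == (2, frozenset({(0, 0), (0, 1)}))  # auto minus overlap
        assert by_area[1] == (2, frozenset({(0, 2), (0, 3)}))  # the added cluster
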