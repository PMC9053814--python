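"""Thresholding against brute-force oracles, and binary cleanup properties."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

from blebquant import (
    ImageStack,
    auto_threshold,
    binarize_stack,
    fill_holes,
    remove_attached_noise,
    segment_whole_cell,
    size_exclude,
)


def otsu_bruteforce(frame):
    """Independent oracle: exhaustive between-class-variance maximization.

    Scans every cut point of the 256-bin histogram over the frame's
    intensity range with plain python loops.
    """
    lo, hi = float(frame.min()), float(frame.max())
    counts, edges = np.histogram(frame.ravel(), bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_k = -1.0, 0
    total = counts.sum()
    for k in range(256):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return centers[best_k]


class TestAutoThreshold:
    def test_otsu_separates_perfectly_bimodal_frame(self):
        frame = np.array([10] * 100 + [200] * 100, dtype=np.uint8).reshape(10, 20)
        t = auto_threshold(frame, "otsu")
        assert 10 <= t < 200
        assert ((frame > t) == (frame == 200)).all()

    def test_mean_is_the_arithmetic_mean(self):
        frame = np.array([10] * 100 + [200] * 100, dtype=np.uint8).reshape(10, 20)
        assert auto_threshold(frame, "mean") == pytest.approx(105.0)

    def test_otsu_matches_bruteforce_on_specified_histogram(self, rng):
        values = np.concatenate(
            [np.full(50, 0), np.full(30, 64), np.full(10, 128), np.full(10, 255)]
        ).astype(np.uint8)
        frame = rng.permutation(values).reshape(10, 10)
        assert auto_threshold(frame, "otsu") == pytest.approx(otsu_bruteforce(frame))

    @pytest.mark.parametrize("seed", range(10))
    def test_otsu_matches_bruteforce_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        assert auto_threshold(frame, "otsu") == pytest.approx(otsu_bruteforce(frame))

    def test_constant_frame_raises_with_frame_index(self):
        with pytest.raises(ValueError, match="frame 3"):
            auto_threshold(np.full((8, 8), 42, dtype=np.uint8), "otsu", frame_index=3)

    @pytest.mark.parametrize("method", ["otsu", "mean", "li", "triangle", "yen", "isodata"])
    def test_all_methods_lie_within_intensity_range(self, method, rng):
        frame = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        t = auto_threshold(frame, method)
        assert frame.min() <= t < frame.max()

    def test_unknown_method_rejected(self, rng):
        frame = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        with pytest.raises(ValueError, match="unknown threshold method"):
            auto_threshold(frame, "magic")


class TestBinarizeStack:
    def test_identical_frames_give_identical_masks_in_both_modes(self, rng):
        frame = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        stack = ImageStack(np.stack([frame, frame]))
        for mode in ("first_frame", "per_frame"):
            mask, report = binarize_stack(stack, "otsu", mode=mode)
            np.testing.assert_array_equal(mask.frames[0], mask.frames[1])
            assert report.mode == mode

    def test_first_frame_threshold_propagates(self):
        f0 = np.array([10] * 100 + [200] * 100, dtype=np.uint8).reshape(10, 20)
        f1 = np.array([10] * 100 + [90] * 100, dtype=np.uint8).reshape(10, 20)
        stack = ImageStack(np.stack([f0, f1]))
        t0 = otsu_bruteforce(f0)
        mask, report = binarize_stack(stack, "otsu", mode="first_frame")
        assert report.values == {0: pytest.approx(t0)}
        if t0 > 90:
            assert not mask.frames[1].any()

    def test_per_frame_equals_framewise_definition(self, rng):
        frames = rng.integers(0, 256, size=(3, 16, 16)).astype(np.uint8)
        stack = ImageStack(frames)
        mask, report = binarize_stack(stack, "otsu", mode="per_frame")
        for t in range(3):
            tv = auto_threshold(frames[t], "otsu")
            assert report.values[t] == pytest.approx(tv)
            np.testing.assert_array_equal(mask.frames[t], frames[t] > tv)

    def test_dark_cell_polarity_inverts_selection(self):
        frame = np.array([10] * 100 + [200] * 100, dtype=np.uint8).reshape(10, 20)
        stack = ImageStack(frame[None])
        mask, _ = binarize_stack(stack, "otsu", polarity="dark_cell")
        assert ((frame == 10) == mask.frames[0]).all()


class TestCleanup:
    def test_fill_holes_fills_ring_interior(self):
        frame = np.zeros((5, 5), dtype=bool)
        frame[1:4, 1:4] = True
        frame[2, 2] = False
        filled = fill_holes(frame)
        assert filled[2, 2]
        assert filled.sum() == 9

    def test_fill_holes_idempotent_and_identity_on_solid(self, rng):
        solid = np.zeros((8, 8), dtype=bool)
        solid[2:6, 2:6] = True
        np.testing.assert_array_equal(fill_holes(solid), solid)
        blob = rng.random((32, 32)) > 0.4
        once = fill_holes(blob)
        np.testing.assert_array_equal(fill_holes(once), once)
        empty = np.zeros((6, 6), dtype=bool)
        np.testing.assert_array_equal(fill_holes(empty), empty)

    def test_size_exclude_keep_largest(self):
        frame = np.zeros((20, 40), dtype=bool)
        frame[1:11, 1:11] = True  # 100 px
        frame[1:4, 20:24] = True  # 12 px
        frame[15:16, 30:33] = True  # 3 px
        kept = size_exclude(frame, "keep_largest")
        assert kept.sum() == 100
        assert kept[1:11, 1:11].all()

    def test_size_exclude_min_area(self):
        frame = np.zeros((20, 40), dtype=bool)
        frame[1:11, 1:11] = True
        frame[1:4, 20:24] = True
        frame[15:16, 30:33] = True
        kept = size_exclude(frame, "min_area", min_area_um2=10.0, pixel_size_um=1.0)
        assert kept.sum() == 112

    def test_size_exclude_single_component_identity(self, rng):
        frame = np.zeros((16, 16), dtype=bool)
        frame[4:9, 4:9] = True
        np.testing.assert_array_equal(size_exclude(frame, "keep_largest"), frame)
        np.testing.assert_array_equal(
            size_exclude(frame, "min_area", min_area_um2=1.0), frame
        )

    def test_size_exclude_empty_frame_warns_and_returns_empty(self, caplog):
        frame = np.zeros((8, 8), dtype=bool)
        with caplog.at_level("WARNING", logger="blebquant.segmentation"):
            out = size_exclude(frame, "keep_largest")
        assert not out.any()
        assert any("empty frame" in r.message for r in caplog.records)

    def test_opening_radius_zero_is_identity(self, rng):
        frame = rng.random((16, 16)) > 0.5
        np.testing.assert_array_equal(remove_attached_noise(frame, 0), frame)

    def test_opening_removes_thin_spur_like_erosion_then_dilation(self):
        frame = np.zeros((30, 40), dtype=bool)
        frame[5:25, 5:25] = True  # 20x20 square
        frame[14, 25:30] = True  # 1-px spur
        opened = remove_attached_noise(frame, 1)
        footprint = disk(1)
        oracle = ndimage.binary_dilation(
            ndimage.binary_erosion(frame, footprint), footprint
        )
        np.testing.assert_array_equal(opened, oracle)
        # spur gone except its root pixel, which the square edge shields
        assert not opened[14, 26:30].any()
        assert opened[6:24, 6:24].all()

    def test_opening_annihilates_objects_thinner_than_disk(self):
        frame = np.zeros((10, 30), dtype=bool)
        frame[5, 2:28] = True  # 1-px-wide line
        assert not remove_attached_noise(frame, 1).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_opening_is_antiextensive_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        frame = ndimage.binary_dilation(rng.random((32, 32)) > 0.9, iterations=2)
        opened = remove_attached_noise(frame, 2)
        assert not (opened & ~frame).any()  # output subset of input
        np.testing.assert_array_equal(remove_attached_noise(opened, 2), opened)


class TestSegmentWholeCell:
    def test_whole_cell_mask_has_single_component(self, rng):
        from skimage.measure import label

        frame = np.full((64, 64), 20.0)
        frame[20:44, 20:44] = 120.0
        frame[50:53, 5:8] = 120.0  # debris removed by keep_largest
        noisy = frame + rng.normal(0, 5, frame.shape)
        stack = ImageStack(np.stack([noisy, noisy]))
        whole, raw, report = segment_whole_cell(stack)
        for t in range(2):
            assert label(whole.frames[t], connectivity=2).max() == 1
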