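"""2.5D sample extraction, cropping, pyramids, and online augmentation."""

import numpy as np
import pytest

from qsmseg.dataio import LabelMap, Volume
from qsmseg.preprocess import (AugmentParams, AugmentRanges, SliceSample,
                               apply_augment, center_crop, extract_slices,
                               multiscale_inputs, normalize_intensity,
                               sample_augment)


def _volume(shape=(32, 32, 6)):
    data = np.arange(np.prod(shape), dtype=np.float32).reshape(shape)
    return Volume(data, (1.0, 1.0, 1.0))


class TestCenterCrop:
    def test_shapes(self):
        img = np.zeros((288, 240), dtype=np.float32)
        assert center_crop(img, 96).shape == (96, 96)

    def test_identity_when_crop_equals_size(self):
        img = np.random.default_rng(0).normal(size=(16, 16))
        np.testing.assert_array_equal(center_crop(img, 16), img)

    def test_odd_remainder_puts_extra_pixel_high(self):
        img = np.arange(7 * 7, dtype=float).reshape(7, 7)
        # start index floor((7-4)/2) = 1 -> rows/cols 1..4, extra pixel on high side
        np.testing.assert_array_equal(center_crop(img, 4), img[1:5, 1:5])

    def test_too_large_crop_rejected(self):
        with pytest.raises(ValueError):
            center_crop(np.zeros((8, 8)), 9)


class TestExtractSlices:
    def test_all_selection_yields_one_sample_per_slice(self):
        vol = _volume()
        lab = LabelMap(np.zeros(vol.data.shape, dtype=np.uint8))
        samples = extract_slices(vol, lab, crop=16)
        assert len(samples) == vol.data.shape[2]
        assert all(s.stack.shape == (3, 16, 16) for s in samples)

    def test_edge_slices_replicate_neighbours(self):
        vol = _volume()
        samples = extract_slices(vol, None, crop=32)
        first = samples[0]
        np.testing.assert_array_equal(first.stack[0], first.stack[1])
        np.testing.assert_array_equal(first.stack[2], vol.data[:, :, 1])
        last = samples[-1]
        np.testing.assert_array_equal(last.stack[1], last.stack[2])

    def test_truth_is_middle_slice(self):
        vol = _volume()
        lab_data = np.zeros(vol.data.shape, dtype=np.uint8)
        lab_data[10:14, 10:14, 3] = 1
        samples = extract_slices(vol, LabelMap(lab_data), crop=32)
        np.testing.assert_array_equal(samples[3].truth, lab_data[:, :, 3])
        assert samples[2].truth.sum() == 0

    def test_roi_with_margin_selects_enumerated_indices(self):
        vol = _volume((32, 32, 100))
        lab_data = np.zeros(vol.data.shape, dtype=np.uint8)
        lab_data[8:12, 8:12, 40:61] = 1  # ROI on slices 40..60
        samples = extract_slices(vol, LabelMap(lab_data), crop=16,
                                 selection="roi_with_margin", margin=3)
        assert [s.slice_index for s in samples] == list(range(37, 64))

    def test_crop_larger_than_plane_rejected(self):
        with pytest.raises(ValueError):
            extract_slices(_volume(), None, crop=64)


class TestMultiscale:
    def test_pyramid_sizes(self):
        stack = np.random.default_rng(0).normal(size=(3, 96, 96)).astype(np.float32)
        scales = multiscale_inputs(stack)
        assert [s.shape[1] for s in scales] == [96, 48, 24, 12]
        assert all(s.shape[0] == 3 for s in scales)

    def test_constant_preserved_and_mean_preserved(self):
        const = np.full((3, 16, 16), 7.5, dtype=np.float32)
        for s in multiscale_inputs(const):
            np.testing.assert_allclose(s, 7.5)
        stack = np.random.default_rng(1).normal(size=(3, 16, 16)).astype(np.float32)
        for s in multiscale_inputs(stack):
            assert s.mean() == pytest.approx(stack.mean(), abs=1e-5)

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError):
            multiscale_inputs(np.zeros((3, 20, 20), dtype=np.float32))


class TestNormalize:
    def test_affine_mapping(self):
        lo, hi = -0.3, 0.5
        assert normalize_intensity(np.full((1, 2, 2), lo), (lo, hi)).max() == 0.0
        assert normalize_intensity(np.full((1, 2, 2), hi), (lo, hi)).min() == 1.0
        mid = normalize_intensity(np.full((1, 2, 2), (lo + hi) / 2), (lo, hi))
        np.testing.assert_allclose(mid, 0.5)

    def test_monotone_and_clipped(self, rng):
        x = rng.normal(0, 1, size=(3, 8, 8)).astype(np.float32)
        y = normalize_intensity(x, (-0.5, 0.5))
        assert y.min() >= 0 and y.max() <= 1
        flat_order = np.argsort(x.ravel())
        assert np.all(np.diff(y.ravel()[flat_order]) >= 0)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.zeros((1, 2, 2)), (0.5, 0.5))


def _sample(size=32):
    rng = np.random.default_rng(3)
    stack = rng.normal(size=(3, size, size)).astype(np.float32)
    truth = np.zeros((size, size), dtype=np.uint8)
    truth[10:16, 12:20] = 1
    return SliceSample(stack, truth, "sub-000", 5)


class TestAugment:
    def test_identity_params_return_sample_unchanged(self):
        s = _sample()
        out = apply_augment(s, AugmentParams(0, 0, 0, 1.0))
        np.testing.assert_array_equal(out.stack, s.stack)
        np.testing.assert_array_equal(out.truth, s.truth)

    def test_draws_stay_inside_configured_ranges(self, rng):
        ranges = AugmentRanges()
        draws = [sample_augment(rng, ranges) for _ in range(10_000)]
        dx = [d.dx for d in draws]
        rot = [d.rotation_deg for d in draws]
        sh = [d.shear for d in draws]
        assert -15 <= min(dx) and max(dx) <= 15
        assert -10 <= min(rot) and max(rot) <= 10
        assert 0.8 <= min(sh) and max(sh) <= 1.2
        # draws are uniform enough to approach the range ends
        assert min(dx) < -14.5 and max(dx) > 14.5
        assert min(rot) < -9.5 and max(rot) > 9.5
        assert min(sh) < 0.81 and max(sh) > 1.19

    def test_integer_shift_preserves_foreground_count(self):
        s = _sample()
        out = apply_augment(s, AugmentParams(5, -3, 0, 1.0))
        assert out.truth.sum() == s.truth.sum()

    def test_same_transform_applied_to_channels_and_truth(self):
        # encode the truth as an image channel: after a pure integer shift
        # the bilinear channel must match the nearest-neighbour truth exactly
        truth = _sample().truth
        s = SliceSample(np.stack([truth, truth, truth]).astype(np.float32),
                        truth, "sub-000", 0)
        out = apply_augment(s, AugmentParams(4, 7, 0, 1.0))
        for ch in out.stack:
            np.testing.assert_array_equal(ch.astype(np.uint8), out.truth)

    def test_out_of_range_params_rejected(self):
        s = _sample()
        for bad in [AugmentParams(16, 0, 0, 1.0), AugmentParams(0, 0, 11, 1.0),
                    AugmentParams(0, 0, 0, 1.3)]:
            with pytest.raises(ValueError):
                apply_augment(s, bad)

    def test_rotation_is_label_consistent(self):
        from qsmseg.metrics import dice_coefficient

        truth = _sample().truth
        s = SliceSample(np.stack([truth] * 3).astype(np.float32), truth, "s", 0)
        out = apply_augment(s, AugmentParams(0, 0, 8.0, 1.1))
        # the truth transformed with NN stays aligned with the transformed
        # intensity foreground (bilinear, thresholded at 0.5)
        d = dice_coefficient(out.stack[1] >= 0.5, out.truth > 0)
        assert d > 0.95


# ------------------------------------------------------------ property tests
from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(-5, 5), st.floats(-5, 5))
def test_normalize_is_monotone_pointwise(a, b):
    lo, hi = -0.3, 0.5
    na = normalize_intensity(np.full((1, 1, 1), a), (lo, hi))[0, 0, 0]
    nb = normalize_intensity(np.full((1, 1, 1), b), (lo, hi))[0, 0, 0]
    assert 0.0 <= na <= 1.0
    if a <= b:
        assert na <= nb


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(2, 20), st.integers(2, 20), st.integers(1, 20))
def test_center_crop_shape_and_content(h, w, crop):
    img = np.arange(h * w, dtype=float).reshape(h, w)
    if crop > min(h, w):
        with pytest.raises(ValueError):
            center_crop(img, crop)
        return
    out = center_crop(img, crop)
    assert out.shape == (crop, crop)
    r0, c0 = (h - crop) // 2, (w - crop) // 2
    np.testing.assert_array_equal(out, img[r0:r0 + crop, c0:c0 + crop])
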