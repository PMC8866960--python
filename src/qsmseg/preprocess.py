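"""Volume -> network-ready 2.5D samples.

Each training/inference unit is a stack of three consecutive in-plane slices
(channels) center-cropped to the domain crop size, with the ground truth of
the middle slice. Online augmentation (shift/rotation/shear) is drawn fresh
for every sample in every epoch; intensities use bilinear interpolation and
labels nearest-neighbour so augmentation is label-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import LabelMap, Volume

__all__ = [
    "SliceSample", "AugmentParams", "AugmentRanges",
    "center_crop", "extract_slices", "multiscale_inputs",
    "sample_augment", "apply_augment", "normalize_intensity",
]


@dataclass
class SliceSample:
    """3-channel slice stack plus the middle slice's ground truth."""

    stack: np.ndarray          # (3, crop, crop) float32
    truth: np.ndarray | None   # (crop, crop) uint8, None at inference time
    subject_id: str
    slice_index: int


def center_crop(image: np.ndarray, crop: int) -> np.ndarray:
    """Central ``crop x crop`` window; odd remainders leave the extra pixel
    on the high side (start index = floor((dim - crop) / 2))."""
    h, w = image.shape[:2]
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} exceeds image dims {(h, w)}")
    r0 = (h - crop) // 2
    c0 = (w - crop) // 2
    return image[r0:r0 + crop, c0:c0 + crop]


def _selected_indices(labels: LabelMap | None, n_slices: int,
                      selection: str, margin: int) -> list[int]:
    if selection == "all":
        return list(range(n_slices))
    if selection == "roi_with_margin":
        if labels is None:
            raise ValueError("roi_with_margin selection requires labels")
        fg = np.where((labels.data > 0).any(axis=(0, 1)))[0]
        if fg.size == 0:
            return []
        lo = max(int(fg.min()) - margin, 0)
        hi = min(int(fg.max()) + margin, n_slices - 1)
        return list(range(lo, hi + 1))
    raise ValueError(f"unknown selection mode {selection!r}")


def extract_slices(volume: Volume, labels: LabelMap | None, crop: int,
                   selection: str = "all", margin: int = 3) -> list[SliceSample]:
    """Build one 2.5D sample per selected slice index k with channel stack
    (k-1, k, k+1); neighbours beyond the volume edge are replicated."""
    data = volume.data
    n_slices = data.shape[2]
    if crop > data.shape[0] or crop > data.shape[1]:
        raise ValueError(f"crop {crop} exceeds in-plane dims {data.shape[:2]}")
    samples = []
    for k in _selected_indices(labels, n_slices, selection, margin):
        idx = [max(k - 1, 0), k, min(k + 1, n_slices - 1)]
        stack = np.stack([center_crop(data[:, :, i], crop) for i in idx]
                         ).astype(np.float32)
        truth = None
        if labels is not None:
            truth = center_crop(labels.data[:, :, k], crop).astype(np.uint8)
        samples.append(SliceSample(stack, truth, subject_id="", slice_index=k))
    return samples


def multiscale_inputs(stack: np.ndarray) -> list[np.ndarray]:
    """Average-pool the stack to scales 1, 1/2, 1/4, 1/8 (mean-preserving)."""
    c, h, w = stack.shape
    if h % 8 or w % 8:
        raise ValueError(f"spatial dims {(h, w)} must be divisible by 8")
    out = [stack]
    cur = stack
    for _ in range(3):
        ch, hh, ww = cur.shape
        cur = cur.reshape(ch, hh // 2, 2, ww // 2, 2).mean(axis=(2, 4))
        out.append(cur.astype(np.float32))
    return out


def normalize_intensity(stack: np.ndarray, clip_ppm: tuple[float, float] = (-0.3, 0.5)
                        ) -> np.ndarray:
    """Clip to ``[lo, hi]`` ppm then map affinely to [0, 1]."""
    lo, hi = clip_ppm
    if lo >= hi:
        raise ValueError("clip range requires lo < hi")
    return ((np.clip(stack, lo, hi) - lo) / (hi - lo)).astype(np.float32)


# ----------------------------------------------------------------- augmentation
@dataclass(frozen=True)
class AugmentRanges:
    """Closed parameter ranges of the online augmentation."""

    shift: float = 15.0      # pixels, +/-
    rotation: float = 10.0   # degrees, +/-
    shear: tuple[float, float] = (0.8, 1.2)  # factor; 1.0 = identity


@dataclass(frozen=True)
class AugmentParams:
    dx: float
    dy: float
    rotation_deg: float
    shear: float

    def is_identity(self) -> bool:
        return self.dx == 0 and self.dy == 0 and self.rotation_deg == 0 and self.shear == 1.0


def sample_augment(rng: np.random.Generator,
                   ranges: AugmentRanges = AugmentRanges()) -> AugmentParams:
    """Draw augmentation parameters uniformly within the configured ranges."""
    return AugmentParams(
        dx=float(rng.uniform(-ranges.shift, ranges.shift)),
        dy=float(rng.uniform(-ranges.shift, ranges.shift)),
        rotation_deg=float(rng.uniform(-ranges.rotation, ranges.rotation)),
        shear=float(rng.uniform(*ranges.shear)),
    )


def _validate_params(params: AugmentParams, ranges: AugmentRanges) -> None:
    if abs(params.dx) > ranges.shift or abs(params.dy) > ranges.shift:
        raise ValueError(f"shift {params.dx, params.dy} outside +/-{ranges.shift}")
    if abs(params.rotation_deg) > ranges.rotation:
        raise ValueError(f"rotation {params.rotation_deg} outside +/-{ranges.rotation}")
    if not ranges.shear[0] <= params.shear <= ranges.shear[1]:
        raise ValueError(f"shear {params.shear} outside {ranges.shear}")


def _affine_matrix(params: AugmentParams, shape: tuple[int, int]):
    """Inverse (output -> input) mapping about the image center."""
    theta = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, params.shear - 1.0], [0.0, 1.0]])
    fwd = rot @ shear
    inv = np.linalg.inv(fwd)
    center = (np.asarray(shape) - 1) / 2.0
    offset = center - inv @ (center + np.array([params.dx, params.dy]))
    return inv, offset


def apply_augment(sample: SliceSample, params: AugmentParams,
                  ranges: AugmentRanges = AugmentRanges()) -> SliceSample:
    """Apply one geometric transform to all channels (bilinear) and to the
    truth (nearest-neighbour); out-of-frame pixels are filled with 0."""
    _validate_params(params, ranges)
    if params.is_identity():
        return sample
    inv, offset = _affine_matrix(params, sample.stack.shape[1:])
    stack = np.stack([
        ndimage.affine_transform(ch, inv, offset=offset, order=1, cval=0.0,
                                 mode="constant")
        for ch in sample.stack]).astype(np.float32)
    truth = sample.truth
    if truth is not None:
        truth = ndimage.affine_transform(truth, inv, offset=offset, order=0,
                                         cval=0, mode="constant",
                                         output=np.uint8)
    return SliceSample(stack, truth, sample.subject_id, sample.slice_index)
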