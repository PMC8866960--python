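"""Case-level segmentation: slice prediction, fold ensembling, 3D assembly.

Every slice of a case is preprocessed exactly like the training data, passed
through each of the cross-validation fold models, and the full-resolution
(branch 1) probability maps are averaged pixelwise across folds. The stacked
2D maps form a probability volume which is thresholded at 0.5, resolved by
argmax among classes that pass the threshold, and cleaned per class by
keeping only the largest 3D connected components (26-connectivity; the
default keeps two, one per hemisphere, since every nucleus is bilateral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import LabelMap, Volume
from .network import build_network
from .nn import no_grad
from .preprocess import extract_slices
from .training import ModelBundle, prepare_batch

__all__ = ["ProbabilityVolume", "SegmentationMask", "predict_case",
           "binarize", "largest_components", "segment_case"]


@dataclass
class ProbabilityVolume:
    """Per-class probabilities on the volume grid: (n_classes, R, C, S)."""

    data: np.ndarray
    class_ids: tuple[int, ...]
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SegmentationMask:
    """Per-class binary masks plus provenance of the postprocessing."""

    masks: dict[int, np.ndarray]   # class_id -> bool volume
    voxel_size: tuple[float, float, float]
    threshold: float = 0.5
    top_k: int = 2

    def to_labelmap(self) -> LabelMap:
        out = np.zeros(next(iter(self.masks.values())).shape, dtype=np.uint8)
        for cid in sorted(self.masks):
            out[self.masks[cid]] = cid
        return LabelMap(out, frozenset(self.masks))


def predict_case(volume: Volume, bundle: ModelBundle,
                 batch_size: int = 32) -> ProbabilityVolume:
    """Fold-ensembled probability volume for one case.

    The crop window is un-cropped back into the full grid; voxels outside it
    receive probability 0.
    """
    if not bundle.complete:
        raise ValueError("model bundle is incomplete; cannot predict")
    pp = bundle.preprocess
    crop = pp.crop_size
    rows, cols, n_slices = volume.data.shape
    if crop > rows or crop > cols:
        raise ValueError(f"volume in-plane dims {(rows, cols)} smaller than "
                         f"the bundle's crop size {crop}")
    samples = extract_slices(volume, None, crop, selection="all")
    models = []
    for tf in bundle.folds:
        m = build_network(bundle.network_config)
        m.load_state_dict(tf.state)
        m.eval()
        models.append(m)

    n_classes = bundle.network_config.n_classes
    prob_crop = np.zeros((n_slices, crop, crop, n_classes), dtype=np.float64)
    for start in range(0, len(samples), batch_size):
        batch = samples[start:start + batch_size]
        scales, _ = prepare_batch(batch, pp, rng=None,
                                  use_multiscale=bundle.network_config.use_multiscale_inputs)
        acc = None
        with no_grad():
            for m in models:
                out = m.forward(scales)[0].data  # branch 1: full-res head
                acc = out.astype(np.float64) if acc is None else acc + out
        prob_crop[start:start + len(batch)] = acc / len(models)

    # un-crop: place the (slice, crop, crop, class) block back into the grid
    full = np.zeros((n_classes, rows, cols, n_slices), dtype=np.float32)
    r0 = (rows - crop) // 2
    c0 = (cols - crop) // 2
    full[:, r0:r0 + crop, c0:c0 + crop, :] = prob_crop.transpose(3, 1, 2, 0)
    return ProbabilityVolume(full, tuple(pp.class_ids), volume.voxel_size)


def binarize(prob: ProbabilityVolume, threshold: float = 0.5) -> dict[int, np.ndarray]:
    """Per-class masks: voxel is class-positive iff p >= threshold; where
    several classes pass, the highest-probability class wins."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    passing = prob.data >= threshold
    winner = prob.data.argmax(axis=0)
    masks = {}
    for idx, cid in enumerate(prob.class_ids):
        masks[cid] = passing[idx] & (winner == idx)
    return masks


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def largest_components(masks: dict[int, np.ndarray], top_k: int = 2,
                       voxel_size=(1.0, 1.0, 1.0), threshold: float = 0.5
                       ) -> SegmentationMask:
    """Keep the ``top_k`` largest 26-connected 3D components per class."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    kept = {}
    for cid, mask in masks.items():
        lab, n = ndimage.label(mask, structure=_CONN26)
        if n <= top_k:
            kept[cid] = mask.astype(bool)
            continue
        sizes = np.bincount(lab.ravel())[1:]  # component 1..n
        keep = np.argsort(sizes)[::-1][:top_k] + 1
        kept[cid] = np.isin(lab, keep)
    return SegmentationMask(kept, tuple(voxel_size), threshold, top_k)


def segment_case(volume: Volume, bundle: ModelBundle, threshold: float = 0.5,
                 top_k: int = 2) -> SegmentationMask:
    """Full pipeline: predict -> ensemble -> binarize -> largest components."""
    prob = predict_case(volume, bundle)
    masks = binarize(prob, threshold)
    return largest_components(masks, top_k, volume.voxel_size, threshold)
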