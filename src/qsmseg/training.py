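"""Losses, training loop, cross-validation, and cross-protocol transfer.

The loss is the sum of a soft Dice loss and a mean binary cross-entropy,
computed per class channel and averaged over classes, then combined over the
deep-supervision branches as a weighted sum with default weights
(0.6, 0.3, 0.1). Training uses Adam at an initial learning rate of 1e-4 and
early stopping: the run ends when the validation loss has not set a new
minimum for ``patience`` (default 20) consecutive epochs, and the
best-validation checkpoint is kept.

Transfer learning copies every non-output tensor of a trained source model
(2 classes, low-resolution protocol) bit-exactly into a target model
(3 classes), re-initializes only the prediction heads, and fine-tunes all
weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Tensor, no_grad
from .network import (MultiInputAttentionUNet, NetworkConfig, build_network,
                      is_output_param, load_checkpoint, save_checkpoint)
from .preprocess import (AugmentRanges, SliceSample, apply_augment,
                         normalize_intensity, sample_augment)

__all__ = [
    "LossWeights", "TrainConfig", "PreprocessConfig", "TrainedFold", "ModelBundle",
    "dice_loss", "cross_entropy_loss", "combine_branch_losses", "total_loss",
    "make_batches", "train_fold", "cross_validate", "transfer_weights",
]

DICE_SMOOTH = 1e-6
CE_CLAMP = 1e-7


# ------------------------------------------------------------------- losses
def dice_loss(p, g, smooth: float = DICE_SMOOTH):
    """Soft Dice loss ``1 - 2*sum(p*g) / (sum(p) + sum(g))``.

    Accepts arrays (returns float) or autodiff tensors (returns a Tensor).
    ``smooth`` is added to numerator and denominator so the empty/empty case
    is defined (and equals 0).
    """
    if isinstance(p, Tensor):
        g = g.data if isinstance(g, Tensor) else np.asarray(g, dtype=np.float32)
        num = (p * g).sum() * 2.0 + smooth
        den = p.sum() + float(g.sum()) + smooth
        return 1.0 - num / den
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    return float(1.0 - (2.0 * (p * g).sum() + smooth) / (p.sum() + g.sum() + smooth))


def cross_entropy_loss(p, g, clamp: float = CE_CLAMP):
    """Mean binary cross-entropy with probabilities clamped away from 0/1."""
    if isinstance(p, Tensor):
        g = g.data if isinstance(g, Tensor) else np.asarray(g, dtype=np.float32)
        pc = p.clip(clamp, 1.0 - clamp)
        return -((pc.log() * g) + ((1.0 - pc).log() * (1.0 - g))).mean()
    p = np.clip(np.asarray(p, dtype=np.float64), clamp, 1.0 - clamp)
    g = np.asarray(g, dtype=np.float64)
    return float(-np.mean(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)))


@dataclass(frozen=True)
class LossWeights:
    """Branch weights (lambda_1, lambda_2, lambda_3) of the total loss."""

    l1: float = 0.6
    l2: float = 0.3
    l3: float = 0.1

    def __post_init__(self):
        vals = (self.l1, self.l2, self.l3)
        if any(v < 0 for v in vals) or not any(v > 0 for v in vals):
            raise ValueError("weights must be non-negative with at least one positive")

    def as_tuple(self):
        return (self.l1, self.l2, self.l3)


def combine_branch_losses(branch_losses, weights: LossWeights = LossWeights()):
    """Weighted sum ``sum_b lambda_b * Loss_b``.

    With a single branch (deep supervision off) the first weight is
    renormalized to 1 so the total equals the branch loss.
    """
    n = len(branch_losses)
    if n == 1:
        return branch_losses[0]
    lam = weights.as_tuple()
    if n != len(lam):
        raise ValueError(f"{n} branch losses but {len(lam)} weights")
    total = branch_losses[0] * lam[0]
    for loss_b, w in zip(branch_losses[1:], lam[1:]):
        total = total + loss_b * w
    return total


def _branch_loss(p: Tensor, g: np.ndarray) -> Tensor:
    """Mean over class channels of (Dice loss + cross-entropy)."""
    k = p.shape[-1]
    losses = []
    for c in range(k):
        pc = _take_channel(p, c)
        gc = g[..., c]
        losses.append(dice_loss(pc, gc) + cross_entropy_loss(pc, gc))
    total = losses[0]
    for lo in losses[1:]:
        total = total + lo
    return total * (1.0 / k)


def _take_channel(t: Tensor, c: int) -> Tensor:
    def make(_out):
        def _backward(g):
            full = np.zeros_like(t.data)
            full[..., c] = g
            t._accum(full)
        return _backward

    return Tensor._node(t.data[..., c], (t,), make)


def total_loss(branch_outputs, truth_onehot, weights: LossWeights = LossWeights(),
               per_nucleus: bool = False):
    """Deep-supervision total loss over branch probability maps.

    ``branch_outputs``: list of (B, H, W, K) tensors (or (B, H, W, 1) per
    branch when ``per_nucleus``); ``truth_onehot``: (B, H, W, K) binary.
    """
    if per_nucleus:
        if len(branch_outputs) != truth_onehot.shape[-1]:
            raise ValueError("per-nucleus mode needs one branch per class")
        losses = [_branch_loss(p, truth_onehot[..., b:b + 1])
                  for b, p in enumerate(branch_outputs)]
    else:
        losses = [_branch_loss(p, truth_onehot) for p in branch_outputs]
    return combine_branch_losses(losses, weights)


# ------------------------------------------------------------ configuration
@dataclass(frozen=True)
class PreprocessConfig:
    """Slice-pipeline settings shared by training and inference."""

    crop_size: int
    class_ids: tuple[int, ...]
    normalize_range: tuple[float, float] | None = (-0.3, 0.5)
    augment: AugmentRanges = field(default_factory=AugmentRanges)
    selection: str = "all"
    selection_margin: int = 3


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    initial_lr: float = 1e-4
    patience: int = 20
    max_epochs: int = 300
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.batch_size < 1 or self.patience < 1:
            raise ValueError("batch_size and patience must be >= 1")


@dataclass
class TrainedFold:
    fold_index: int
    state: dict[str, np.ndarray]
    best_val_loss: float
    epoch_log: list[dict]

    def __post_init__(self):
        if self.epoch_log:
            best = min(e["val_loss"] for e in self.epoch_log)
            if not np.isclose(best, self.best_val_loss):
                raise ValueError("best_val_loss must be the epoch-log minimum")


@dataclass
class ModelBundle:
    """Architecture + one trained weight set per cross-validation fold."""

    network_config: NetworkConfig
    preprocess: PreprocessConfig
    folds: list[TrainedFold]
    complete: bool = True

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for tf in self.folds:
            model = build_network(self.network_config)
            model.load_state_dict(tf.state)
            save_checkpoint(out_dir / f"fold_{tf.fold_index}" / "best.ckpt", model)
            log_path = out_dir / f"fold_{tf.fold_index}" / "epochs.csv"
            with open(log_path, "w") as fh:
                fh.write("epoch,train_loss,val_loss\n")
                for e in tf.epoch_log:
                    fh.write(f"{e['epoch']},{e['train_loss']:.6f},{e['val_loss']:.6f}\n")
        meta = {
            "n_folds": len(self.folds),
            "complete": self.complete,
            "best_val_losses": [tf.best_val_loss for tf in self.folds],
            "preprocess": {
                "crop_size": self.preprocess.crop_size,
                "class_ids": list(self.preprocess.class_ids),
                "normalize_range": list(self.preprocess.normalize_range)
                if self.preprocess.normalize_range else None,
            },
        }
        (out_dir / "bundle.json").write_text(json.dumps(meta, indent=2) + "\n")
        return out_dir

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "ModelBundle":
        bundle_dir = Path(bundle_dir)
        meta = json.loads((bundle_dir / "bundle.json").read_text())
        folds = []
        net_cfg = None
        for k in range(meta["n_folds"]):
            cfg, state = load_checkpoint(bundle_dir / f"fold_{k}" / "best.ckpt")
            net_cfg = cfg
            folds.append(TrainedFold(k, state, meta["best_val_losses"][k],
                                     epoch_log=[]))
        pp = meta["preprocess"]
        preproc = PreprocessConfig(
            crop_size=pp["crop_size"], class_ids=tuple(pp["class_ids"]),
            normalize_range=tuple(pp["normalize_range"]) if pp["normalize_range"] else None)
        return cls(net_cfg, preproc, folds, complete=meta["complete"])


# ------------------------------------------------------------------ batching
def _downsample_batch(x: np.ndarray) -> np.ndarray:
    b, h, w, c = x.shape
    return x.reshape(b, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4)).astype(np.float32)


def multiscale_batch(x: np.ndarray, n_scales: int = 4) -> list[np.ndarray]:
    """NHWC batch -> [1, 1/2, ..., 1/2^(n-1)] average-pooled pyramids."""
    out = [x]
    for _ in range(n_scales - 1):
        out.append(_downsample_batch(out[-1]))
    return out


def prepare_batch(samples: list[SliceSample], preproc: PreprocessConfig,
                  rng: np.random.Generator | None = None,
                  use_multiscale: bool = True):
    """Samples -> (input scale list, one-hot truth); augments when rng given."""
    stacks, truths = [], []
    for s in samples:
        if rng is not None:
            s = apply_augment(s, sample_augment(rng, preproc.augment), preproc.augment)
        stack = s.stack
        if preproc.normalize_range is not None:
            stack = normalize_intensity(stack, preproc.normalize_range)
        stacks.append(stack.transpose(1, 2, 0))  # CHW -> HWC
        if s.truth is not None:
            onehot = np.stack([(s.truth == cid) for cid in preproc.class_ids],
                              axis=-1).astype(np.float32)
            truths.append(onehot)
    x = np.stack(stacks)
    scales = multiscale_batch(x) if use_multiscale else [x]
    y = np.stack(truths) if truths else None
    return scales, y


# ------------------------------------------------------------------ training
def _epoch_loss(model, samples, preproc, config, rng, train: bool,
                optimizer=None) -> float:
    per_nucleus = model.config.head_mode == "per_nucleus"
    n = len(samples)
    order = rng.permutation(n) if train else np.arange(n)
    losses, weights = [], []
    bs = config.batch_size
    for start in range(0, n, bs):
        batch = [samples[i] for i in order[start:start + bs]]
        scales, y = prepare_batch(batch, preproc, rng if train else None,
                                  model.config.use_multiscale_inputs)
        if train:
            outputs = model.forward(scales)
            loss = total_loss(outputs, y, config.loss_weights, per_nucleus)
        else:
            with no_grad():
                outputs = model.forward(scales)
                loss = total_loss(outputs, y, config.loss_weights, per_nucleus)
        value = loss.item()
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite training loss ({value}); aborting")
        if train:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        losses.append(value)
        weights.append(len(batch))
    return float(np.average(losses, weights=weights))


def train_fold(model: MultiInputAttentionUNet, fit_samples: list[SliceSample],
               val_samples: list[SliceSample], config: TrainConfig,
               preproc: PreprocessConfig, fold_index: int = 0) -> TrainedFold:
    """Train one fold with Adam + early stopping; returns the best-epoch state."""
    if not fit_samples or not val_samples:
        raise ValueError("fit and validation sample sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, fold_index, 7]))
    optimizer = Adam(model.parameters(), lr=config.initial_lr)
    best_val = np.inf
    best_state = None
    since_best = 0
    log: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        train_loss = _epoch_loss(model, fit_samples, preproc, config, rng,
                                 train=True, optimizer=optimizer)
        model.eval()
        val_loss = _epoch_loss(model, val_samples, preproc, config, rng, train=False)
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.load_state_dict(best_state)
    return TrainedFold(fold_index, best_state, float(best_val), log)


def cross_validate(samples_by_subject: dict[str, list[SliceSample]], split,
                   network_config: NetworkConfig, train_config: TrainConfig,
                   preproc: PreprocessConfig,
                   init_state: dict[str, np.ndarray] | None = None) -> ModelBundle:
    """Train one model per fold of ``split``; optionally initialize each fold
    from a source-model state (transfer learning)."""
    folds = []
    complete = True
    for k, (fit_ids, val_ids) in enumerate(split.folds):
        if init_state is not None:
            model = transfer_weights(init_state, network_config,
                                     seed=train_config.seed + k)
        else:
            model = build_network(network_config, seed=train_config.seed + k)
        fit = [s for sid in fit_ids for s in samples_by_subject[sid]]
        val = [s for sid in val_ids for s in samples_by_subject[sid]]
        try:
            folds.append(train_fold(model, fit, val, train_config, preproc, k))
        except RuntimeError:
            complete = False
            raise
    return ModelBundle(network_config, preproc, folds, complete=complete)


# ------------------------------------------------------------------ transfer
def transfer_weights(source: dict[str, np.ndarray] | str | Path,
                     target_config: NetworkConfig, seed: int = 0
                     ) -> MultiInputAttentionUNet:
    """Initialize a target model from a source state dict or checkpoint.

    Every non-output tensor (parameters and batch-norm buffers) is copied
    bit-exactly; prediction heads keep their fresh seeded initialization
    unless their shapes match the source exactly (same class count), in which
    case they are copied too. Nothing is frozen. Architecture mismatches
    outside the heads raise with the offending tensor names.
    """
    if isinstance(source, (str, Path)):
        _, source = load_checkpoint(source)
    source = {k: v for k, v in source.items() if not k.startswith("__")}
    model = build_network(target_config, seed=seed)
    mismatched = []
    for name, p in model.named_parameters():
        if name not in source:
            mismatched.append(f"{name} (missing in source)")
            continue
        if is_output_param(name):
            if source[name].shape == p.data.shape:
                p.data = source[name].astype(np.float32).copy()
            continue
        if source[name].shape != p.data.shape:
            mismatched.append(f"{name} {source[name].shape} vs {p.data.shape}")
            continue
        p.data = source[name].astype(np.float32).copy()
    for name, b in model.named_buffers():
        key = "buffer." + name
        if is_output_param(name) or key not in source:
            continue
        if source[key].shape != b.shape:
            mismatched.append(f"{key} {source[key].shape} vs {b.shape}")
            continue
        b[...] = source[key]
    if mismatched:
        raise ValueError("source/target architecture mismatch beyond output "
                         "layers: " + ", ".join(sorted(mismatched)))
    return model
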