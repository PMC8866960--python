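"""Multi-input attention U-net with deep supervision.

The network is a four-stage 2D U-net over 3-channel (2.5D) slice stacks:

* multi-scale inputs — the stack downsampled 2x/4x/8x is passed through one
  convolution and concatenated with the encoder features at the matching
  resolution, so fine detail lost to pooling re-enters the encoder;
* attention gates — each skip connection is rescaled by a coefficient map
  ``alpha`` in [0, 1]: the skip features x are projected by a 1x1 stride-2
  convolution to the gate signal g's grid, added to g, passed through ReLU, a
  1x1 projection, a sigmoid, and upsampled back to x's grid;
* deep supervision — the last three decoder resolutions each carry a
  prediction head; every head predicts all foreground classes as independent
  sigmoid channels, upsampled to the full crop resolution. Branch 1 is the
  full-resolution head. A per-nucleus head variant (three single-class
  full-resolution heads) is available behind ``head_mode``.

Output-layer parameters are the head convolutions (names starting with
``head``); everything else is shape-identical between the 2-class and 3-class
configurations, which is what makes cross-protocol weight transfer possible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import BatchNorm2d, Conv2d, ConvBlock, Module, Tensor, concat

__all__ = ["NetworkConfig", "AttentionGate", "MultiInputAttentionUNet",
           "build_network", "save_checkpoint", "load_checkpoint",
           "is_output_param"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters."""

    in_channels: int = 3
    n_classes: int = 3
    base_filters: int = 32
    depth: int = 4
    use_attention: bool = True
    use_deep_supervision: bool = True
    use_multiscale_inputs: bool = True
    head_mode: str = "deep_supervision"  # or "per_nucleus"

    def __post_init__(self):
        if self.depth < 1 or self.base_filters < 1 or self.n_classes < 1:
            raise ValueError("depth, base_filters and n_classes must be >= 1")
        if self.head_mode not in ("deep_supervision", "per_nucleus"):
            raise ValueError(f"unknown head_mode {self.head_mode!r}")
        if self.head_mode == "per_nucleus" and self.use_deep_supervision:
            raise ValueError("per_nucleus heads replace deep supervision; "
                             "set use_deep_supervision=False")

    @property
    def n_branches(self) -> int:
        if self.head_mode == "per_nucleus":
            return self.n_classes
        return 3 if self.use_deep_supervision else 1


def is_output_param(name: str) -> bool:
    """True for output-layer (prediction head) parameters."""
    return name.startswith("head")


class AttentionGate(Module):
    """Additive attention gate on a skip connection (see module docstring)."""

    def __init__(self, skip_channels: int, gate_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.project_x = self.add_module(
            "project_x", Conv2d(skip_channels, gate_channels, 1, rng, stride=2))
        self.psi = self.add_module("psi", Conv2d(gate_channels, 1, 1, rng))

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        if (x.shape[1] != 2 * g.shape[1]) or (x.shape[2] != 2 * g.shape[2]):
            raise ValueError(f"skip spatial dims {x.shape[1:3]} must be twice "
                             f"the gate's {g.shape[1:3]}")
        a = (self.project_x(x) + g).relu()
        alpha = self.psi(a).sigmoid().upsample_bilinear(2)
        return x * alpha  # alpha broadcasts over the channel axis

    def coefficients(self, x: Tensor, g: Tensor) -> np.ndarray:
        """The attention coefficient map alpha, upsampled to x's grid."""
        a = (self.project_x(x) + g).relu()
        return self.psi(a).sigmoid().upsample_bilinear(2).data


class MultiInputAttentionUNet(Module):
    """See module docstring. ``forward`` returns one probability map per
    branch, each (B, H, W, n_classes_or_1) in [0, 1] at full resolution."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
        F = config.base_filters
        d = config.depth
        self.enc_channels = [F * 2 ** i for i in range(d)]
        bottleneck_ch = F * 2 ** d

        in_ch = config.in_channels
        self.enc = []
        for i, ch in enumerate(self.enc_channels):
            block_in = in_ch if i == 0 else self.enc_channels[i - 1]
            if config.use_multiscale_inputs and i > 0:
                block_in += F
            self.enc.append(self.add_module(f"enc{i}", ConvBlock(block_in, ch, rng)))
        if config.use_multiscale_inputs:
            self.inject = [self.add_module(f"inject{i}",
                                           Conv2d(config.in_channels, F, 3, rng, padding=1))
                           for i in range(1, d)]
        self.bottleneck = self.add_module(
            "bottleneck", ConvBlock(self.enc_channels[-1], bottleneck_ch, rng))

        self.dec = []
        self.gates = []
        up_ch = bottleneck_ch
        for i in reversed(range(d)):
            skip_ch = self.enc_channels[i]
            if config.use_attention:
                self.gates.append(self.add_module(f"gate{i}",
                                                  AttentionGate(skip_ch, up_ch, rng)))
            else:
                self.gates.append(None)
            self.dec.append(self.add_module(f"dec{i}",
                                            ConvBlock(up_ch + skip_ch, skip_ch, rng)))
            up_ch = skip_ch
        self.gates = list(reversed(self.gates))  # index by encoder level
        self.dec = list(reversed(self.dec))

        if config.head_mode == "per_nucleus":
            self.heads = [self.add_module(f"head{b}", Conv2d(self.enc_channels[0],
                                                             1, 1, rng))
                          for b in range(config.n_classes)]
            self.head_levels = [0] * config.n_classes
        else:
            self.head_levels = [0, 1, 2] if config.use_deep_supervision else [0]
            self.heads = [self.add_module(f"head{b}",
                                          Conv2d(self.enc_channels[lvl],
                                                 config.n_classes, 1, rng))
                          for b, lvl in enumerate(self.head_levels)]

    # ------------------------------------------------------------------ forward
    def __call__(self, inputs) -> list[Tensor]:
        return self.forward(inputs)

    def forward(self, inputs) -> list[Tensor]:
        """``inputs``: a Tensor/array (full-resolution stack, B x H x W x C) or
        the list of multi-scale stacks [1, 1/2, 1/4, 1/8] when multi-scale
        injection is enabled."""
        cfg = self.config
        if isinstance(inputs, (list, tuple)):
            scales = [x if isinstance(x, Tensor) else Tensor(x) for x in inputs]
        else:
            scales = [inputs if isinstance(inputs, Tensor) else Tensor(inputs)]
        x0 = scales[0]
        if x0.shape[1] % (2 ** cfg.depth) or x0.shape[2] % (2 ** cfg.depth):
            raise ValueError(f"input spatial dims {x0.shape[1:3]} must be "
                             f"divisible by {2 ** cfg.depth}")
        if cfg.use_multiscale_inputs:
            if len(scales) != cfg.depth:
                raise ValueError(f"expected {cfg.depth} input scales, got {len(scales)}")
            for i, s in enumerate(scales):
                if s.shape[1] != x0.shape[1] // 2 ** i:
                    raise ValueError(f"scale {i} has wrong spatial size {s.shape[1:3]}")

        skips = []
        h = x0
        for i, block in enumerate(self.enc):
            if i > 0:
                h = h.maxpool2()
                if cfg.use_multiscale_inputs:
                    h = concat([h, self.inject[i - 1](scales[i])], axis=3)
            h = block(h)
            skips.append(h)
        h = self.bottleneck(skips[-1].maxpool2())

        dec_feats: dict[int, Tensor] = {}
        for i in reversed(range(cfg.depth)):
            skip = skips[i]
            if self.gates[i] is not None:
                skip = self.gates[i](skip, h)
            h = concat([h.upsample_bilinear(2), skip], axis=3)
            h = self.dec[i](h)
            dec_feats[i] = h

        outputs = []
        for head, lvl in zip(self.heads, self.head_levels):
            p = head(dec_feats[lvl]).sigmoid()
            if lvl > 0:
                p = p.upsample_bilinear(2 ** lvl)
            outputs.append(p)
        return outputs


def build_network(config: NetworkConfig, seed: int = 0) -> MultiInputAttentionUNet:
    """Build a seeded model; identical (config, seed) gives identical weights."""
    return MultiInputAttentionUNet(config, seed=seed)


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(path: str | Path, model: MultiInputAttentionUNet) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:  # keep the exact filename (no .npz suffix)
        np.savez(fh, **state)
    return path


def load_checkpoint(path: str | Path) -> tuple[NetworkConfig, dict[str, np.ndarray]]:
    with np.load(Path(path), allow_pickle=False) as npz:
        state = {k: npz[k] for k in npz.files}
    cfg = NetworkConfig(**json.loads(state.pop("__config__").tobytes().decode()))
    return cfg, state
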