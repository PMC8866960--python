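"""Neural-network layers built on the autodiff engine.

Modules hold named parameters (trainable :class:`Tensor` leaves) and named
buffers (plain arrays such as batch-norm running statistics). Names are
hierarchical, dot-separated, and stable across builds — the transfer-learning
machinery relies on them to match tensors between source and target models.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBlock"]


class Module:
    """Minimal module base: parameter/buffer registry + train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def add_module(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True, name=name)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        return self._buffers[name]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for cname, child in self._children.items():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # ----------------------------------------------------------- state dicts
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer." + name] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            arr = state[name]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {name!r}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = np.asarray(arr, dtype=np.float32).copy()
        for name, b in self.named_buffers():
            key = "buffer." + name
            if key in state:
                b[...] = state[key]


class Conv2d(Module):
    """2D convolution (NHWC, weight ``(k, k, in, out)``) with He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(kernel_size, kernel_size,
                                       in_channels, out_channels))
        self.weight = self.register_parameter("weight", w.astype(np.float32))
        self.bias = self.register_parameter("bias", np.zeros(out_channels, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = self.register_parameter("gamma", np.ones(channels, dtype=np.float32))
        self.beta = self.register_parameter("beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = self.register_buffer("running_mean", np.zeros(channels))
        self.running_var = self.register_buffer("running_var", np.ones(channels))

    def __call__(self, x: Tensor) -> Tensor:
        # NHWC: per-channel statistics over the leading axes
        if self.training:
            red = tuple(range(x.data.ndim - 1))
            mu = x.data.mean(axis=red)
            var = x.data.var(axis=red)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
            return batchnorm(x, self.gamma, self.beta, mu, var, self.eps, True)
        return batchnorm(x, self.gamma, self.beta, self.running_mean,
                         self.running_var, self.eps, False)


class ConvBlock(Module):
    """(conv3x3 -> BN -> ReLU) x 2, the standard U-net stage."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 batch_norm: bool = True):
        super().__init__()
        self.conv1 = self.add_module("conv1", Conv2d(in_channels, out_channels, 3, rng, padding=1))
        self.conv2 = self.add_module("conv2", Conv2d(out_channels, out_channels, 3, rng, padding=1))
        self.bn1 = self.add_module("bn1", BatchNorm2d(out_channels)) if batch_norm else None
        self.bn2 = self.add_module("bn2", BatchNorm2d(out_channels)) if batch_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv1(x)
        if self.bn1 is not None:
            x = self.bn1(x)
        x = x.relu()
        x = self.conv2(x)
        if self.bn2 is not None:
            x = self.bn2(x)
        return x.relu()
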