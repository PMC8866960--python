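"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core of the segmentation network: a small tape-based
autodiff engine providing exactly the operations a 2D encoder–decoder CNN
needs (convolution, batch statistics, pooling, bilinear upsampling,
elementwise nonlinearities, reductions). All arithmetic is float32.

Image tensors use the NHWC layout ``(batch, height, width, channels)``: on a
CPU this keeps the im2col buffers of the convolution nearly contiguous and
lets per-channel parameters broadcast without reshapes.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order and then
releases the tape. Validation and inference passes should run inside
:class:`no_grad`, which skips tape recording entirely.
"""

from __future__ import annotations

import numpy as np

from ._kernels import col2im, im2col

__all__ = ["Tensor", "concat", "batchnorm", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference/validation)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "name", "_grad_shared")

    def __init__(self, data, requires_grad: bool = False, parents=(), name: str | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents = tuple(parents)
        self.name = name
        self._grad_shared = False

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name})"

    def _accum(self, g: np.ndarray) -> None:
        # First contribution aliases g (no copy); the array is marked shared
        # and a fresh array is allocated only if a second contribution
        # arrives. Gradients are never mutated in place after creation, so
        # aliasing is safe.
        if g.dtype != np.float32:
            g = g.astype(np.float32)
        if self.grad is None:
            self.grad = g
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _node(data, parents, make_backward) -> "Tensor":
        """Create an op output; records the tape only when grad is needed.

        ``make_backward`` is called with the output tensor and must return
        the backward closure.
        """
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out = Tensor(data, True, parents)
            out._backward = make_backward(out)
            return out
        return Tensor(data, False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release the tape: drop closures, graph edges and intermediate
        # gradients so the batch's activations are freed immediately (leaf
        # parameters have no _backward and keep their gradients)
        for node in topo:
            if node._backward is not None:
                node._backward = None
                node._parents = ()
                node.grad = None

    # ------------------------------------------------------------ elementwise
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _binary(self, other, fwd, bwd_a, bwd_b) -> "Tensor":
        other = Tensor._lift(other)

        def make(_out):
            def _backward(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(bwd_a(g, self.data, other.data), self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(bwd_b(g, self.data, other.data), other.data.shape))
            return _backward

        return Tensor._node(fwd(self.data, other.data), (self, other), make)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self):
        return self * -1.0

    def square(self) -> "Tensor":
        return self * self

    def sqrt(self) -> "Tensor":
        def make(out):
            def _backward(g):
                self._accum(g * 0.5 / np.maximum(out.data, 1e-12))
            return _backward

        return Tensor._node(np.sqrt(self.data), (self,), make)

    def log(self) -> "Tensor":
        def make(_out):
            def _backward(g):
                self._accum(g / self.data)
            return _backward

        return Tensor._node(np.log(self.data), (self,), make)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through the unclipped region."""
        def make(_out):
            mask = (self.data > lo) & (self.data < hi)

            def _backward(g):
                self._accum(g * mask)
            return _backward

        return Tensor._node(np.clip(self.data, lo, hi), (self,), make)

    def relu(self) -> "Tensor":
        def make(_out):
            def _backward(g):
                self._accum(g * (self.data > 0))
            return _backward

        return Tensor._node(np.maximum(self.data, 0.0), (self,), make)

    def sigmoid(self) -> "Tensor":
        def make(out):
            def _backward(g):
                self._accum(g * out.data * (1.0 - out.data))
            return _backward

        # clamp the logits: sigmoid saturates beyond +/-60 and exp overflows
        z = np.clip(self.data, -60.0, 60.0)
        return Tensor._node(1.0 / (1.0 + np.exp(-z)), (self,), make)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def make(_out):
            def _backward(g):
                if axis is not None and not keepdims:
                    gg = np.expand_dims(g, axis)
                else:
                    gg = g
                self._accum(np.broadcast_to(gg, self.data.shape).astype(np.float32))
            return _backward

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), make)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ convolution
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2D cross-correlation; x (B,H,W,C), weight (k,k,C,F), bias (F,)."""
        x, w = self.data, weight.data
        B, H, W, C = x.shape
        k, _, _, F = w.shape
        s, p = stride, padding
        if p:
            xp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=np.float32)
            xp[:, p:p + H, p:p + W, :] = x
        else:
            xp = x
        Ho = (xp.shape[1] - k) // s + 1
        Wo = (xp.shape[2] - k) // s + 1
        # im2col into a GEMM-friendly layout: (B*Ho*Wo, k*k*C)
        cols = im2col(xp, k, s, Ho, Wo)
        wflat = w.reshape(k * k * C, F)
        y = cols @ wflat
        if bias is not None:
            y += bias.data
        parents = (self, weight) if bias is None else (self, weight, bias)

        def make(_out):
            def _backward(g):
                gr = g.reshape(B * Ho * Wo, F)
                if bias is not None and bias.requires_grad:
                    bias._accum(gr.sum(axis=0))
                if weight.requires_grad:
                    weight._accum((cols.T @ gr).reshape(k, k, C, F))
                if self.requires_grad:
                    dcols = gr @ wflat.T
                    dxp = col2im(dcols, xp.shape, k, s, Ho, Wo)
                    self._accum(dxp[:, p:p + H, p:p + W, :] if p else dxp)
            return _backward

        return Tensor._node(y.reshape(B, Ho, Wo, F), parents, make)

    # ---------------------------------------------------------------- pooling
    def maxpool2(self) -> "Tensor":
        """2x2 max pooling, stride 2; H and W must be even. x (B,H,W,C)."""
        quads = (self.data[:, 0::2, 0::2, :], self.data[:, 0::2, 1::2, :],
                 self.data[:, 1::2, 0::2, :], self.data[:, 1::2, 1::2, :])
        y = np.maximum(np.maximum(quads[0], quads[1]),
                       np.maximum(quads[2], quads[3]))

        def make(out):
            def _backward(g):
                dx = np.zeros_like(self.data)
                taken = np.zeros(out.data.shape, dtype=bool)
                views = (dx[:, 0::2, 0::2, :], dx[:, 0::2, 1::2, :],
                         dx[:, 1::2, 0::2, :], dx[:, 1::2, 1::2, :])
                for q, v in zip(quads, views):
                    hit = (q == out.data) & ~taken   # first-match wins on ties
                    v += g * hit
                    taken |= hit
                self._accum(dx)
            return _backward

        return Tensor._node(y, (self,), make)

    # --------------------------------------------------------------- upsample
    _interp_cache: dict[tuple[int, int], np.ndarray] = {}

    @staticmethod
    def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
        """Dense 1D bilinear interpolation matrix (n_in*factor, n_in)."""
        key = (n_in, factor)
        A = Tensor._interp_cache.get(key)
        if A is None:
            n_out = n_in * factor
            src = (np.arange(n_out) + 0.5) / factor - 0.5
            src = np.clip(src, 0.0, n_in - 1.0)
            i0 = np.floor(src).astype(int)
            i1 = np.minimum(i0 + 1, n_in - 1)
            w1 = (src - i0).astype(np.float32)
            A = np.zeros((n_out, n_in), dtype=np.float32)
            A[np.arange(n_out), i0] += 1.0 - w1
            A[np.arange(n_out), i1] += w1
            Tensor._interp_cache[key] = A
        return A

    def upsample_bilinear(self, factor: int) -> "Tensor":
        """Bilinear upsampling by an integer factor (half-pixel centers).
        x (B,H,W,C)."""
        _, H, W, _ = self.data.shape
        Ah = Tensor._interp_matrix(H, factor)
        Aw = Tensor._interp_matrix(W, factor)
        y = np.einsum("pi,qj,bijc->bpqc", Ah, Aw, self.data, optimize=True)

        def make(_out):
            def _backward(g):
                self._accum(np.einsum("pi,qj,bpqc->bijc", Ah, Aw, g, optimize=True))
            return _backward

        return Tensor._node(y, (self,), make)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
              var: np.ndarray, eps: float, batch_stats: bool) -> Tensor:
    """Fused batch normalization over the leading NHW axes of an NHWC tensor.

    ``mean``/``var`` are per-channel arrays; when ``batch_stats`` is true they
    must be the statistics of ``x`` itself and the backward pass uses the full
    batch-norm Jacobian, otherwise they are constants (running statistics).
    """
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mean) * inv_std
    n = x.data.size // x.data.shape[-1]

    def make(_out):
        def _backward(g):
            red = tuple(range(g.ndim - 1))
            if beta.requires_grad:
                beta._accum(g.sum(axis=red))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=red))
            if x.requires_grad:
                if batch_stats:
                    gsum = g.sum(axis=red) / n
                    gx = (g * xhat).sum(axis=red) / n
                    x._accum((gamma.data * inv_std) * (g - gsum - xhat * gx))
                else:
                    x._accum(g * (gamma.data * inv_std))
        return _backward

    return Tensor._node(xhat * gamma.data + beta.data, (x, gamma, beta), make)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def make(_out):
        def _backward(g):
            for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(gpart)
        return _backward

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), make)
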