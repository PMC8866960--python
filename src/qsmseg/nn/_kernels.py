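"""Gather/scatter helpers for the convolution.

im2col / col2im move the (k x k)-neighbourhood blocks between the padded
NHWC image and the GEMM layout using k^2 large strided block copies, which
is the fastest formulation available to pure NumPy on one core.
"""

from __future__ import annotations

import numpy as np


def im2col(xp: np.ndarray, k: int, s: int, Ho: int, Wo: int) -> np.ndarray:
    """(B, Hp, Wp, C) padded image -> (B*Ho*Wo, k*k*C) patch matrix."""
    B, _, _, C = xp.shape
    cols = np.empty((B, Ho, Wo, k, k, C), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i:i + Ho * s:s, j:j + Wo * s:s, :]
    return cols.reshape(B * Ho * Wo, k * k * C)


def col2im(dcols: np.ndarray, xp_shape, k: int, s: int, Ho: int, Wo: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto the image."""
    B, Hp, Wp, C = xp_shape
    d6 = dcols.reshape(B, Ho, Wo, k, k, C)
    dxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + Ho * s:s, j:j + Wo * s:s, :] += d6[:, :, :, i, j, :]
    return dxp
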