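"""Low-level array ops for the CPU network engine.

Convolutions are stride-1 cross-correlations implemented as im2col + a single
BLAS matmul; the input gradient of a stride-1 convolution is itself a stride-1
convolution with the spatially flipped, channel-transposed kernel, so forward
and backward share one primitive.  Tensors are NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["im2col", "conv2d_forward", "conv2d_input_grad", "conv2d_weight_grad"]


def im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Patch matrix of shape (N*H*W, C*k*k) for a stride-1, zero-padded conv."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
    ho, wo = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * k * k)


def conv2d_forward(
    x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None, pad: int
) -> tuple[np.ndarray, np.ndarray]:
    """y = x * weight (+ bias); returns (y, patch matrix for the weight grad).

    x: (N,C,H,W); weight: (O,C,k,k); y: (N,O,Ho,Wo), stride 1.
    """
    n, _, h, w = x.shape
    o, c, k, _ = weight.shape
    ho, wo = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    if k == 1 and pad == 0:
        cols = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * w, c)
    else:
        cols = im2col(x, k, pad)
    y = cols @ weight.reshape(o, -1).T
    if bias is not None:
        y += bias
    return y.reshape(n, ho, wo, o).transpose(0, 3, 1, 2), cols


def conv2d_input_grad(g: np.ndarray, weight: np.ndarray, pad: int) -> np.ndarray:
    """Gradient w.r.t. x of a stride-1 conv: full correlation with the flipped kernel."""
    k = weight.shape[2]
    w_t = np.ascontiguousarray(weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    gx, _ = conv2d_forward(g, w_t, None, k - 1 - pad)
    return gx


def conv2d_weight_grad(g: np.ndarray, cols: np.ndarray, weight_shape: tuple) -> np.ndarray:
    """Gradient w.r.t. the kernel given the output grad and the cached patch matrix."""
    o = weight_shape[0]
    g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
    return (g2.T @ cols).reshape(weight_shape)
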