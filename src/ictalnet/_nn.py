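"""Minimal NumPy neural-network primitives shared by the autoencoder
and the LSTM: strided 2-D convolution and its exact adjoint (the
transposed convolution), activations, and an Adam optimiser.

Layout is NHWC.  "Same" padding follows the asymmetric convention
(extra padding goes to the bottom/right), so a stride-2 3x3 convolution
maps H -> ceil(H / 2).  The transposed convolution is implemented as
the exact linear adjoint of the strided convolution, which gives the
familiar H -> H * stride upsampling for these shapes and makes the
gradient pair self-consistent (verified by finite differences in the
test suite).
"""

from __future__ import annotations

import numpy as np


def same_pad(h: int, k: int, s: int) -> tuple[int, int]:
    """(before, after) padding so that output size is ceil(h / s)."""
    out = -(-h // s)
    total = max((out - 1) * s + k - h, 0)
    before = total // 2
    return before, total - before


def _cols(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """Sliding k x k patches of a padded NHWC tensor, strided by s.

    Returns shape (N, Ho, Wo, k, k, C).
    """
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # v: (N, H-k+1, W-k+1, C, k, k) -> stride and reorder
    v = v[:, ::s, ::s]
    return np.ascontiguousarray(np.moveaxis(v, 3, 5))


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 2):
    """Strided same-padded convolution.  x: (N,H,W,Ci), w: (k,k,Ci,Co)."""
    k = w.shape[0]
    ph = same_pad(x.shape[1], k, stride)
    pw = same_pad(x.shape[2], k, stride)
    xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
    cols = _cols(xp, k, stride)
    y = np.tensordot(cols, w, axes=([3, 4, 5], [0, 1, 2])) + b
    return y


def conv2d_backward(dy: np.ndarray, x: np.ndarray, w: np.ndarray, stride: int = 2):
    """Gradients of conv2d wrt input, weight and bias."""
    k = w.shape[0]
    ph = same_pad(x.shape[1], k, stride)
    pw = same_pad(x.shape[2], k, stride)
    xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
    cols = _cols(xp, k, stride)
    dw = np.tensordot(cols, dy, axes=([0, 1, 2], [0, 1, 2]))
    db = dy.sum(axis=(0, 1, 2))
    dxp = _scatter_cols(dy, w, xp.shape, stride)
    dx = dxp[:, ph[0] : xp.shape[1] - ph[1], pw[0] : xp.shape[2] - pw[1], :]
    return dx, dw, db


def _scatter_cols(dy: np.ndarray, w: np.ndarray, xp_shape, stride: int) -> np.ndarray:
    """Scatter-add dy @ w.T patches back into a padded-input-shaped tensor."""
    k = w.shape[0]
    n, ho, wo, _ = dy.shape
    dcols = np.tensordot(dy, w, axes=([3], [3]))  # (N,Ho,Wo,k,k,Ci)
    dxp = np.zeros(xp_shape, dtype=dy.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride, :] += dcols[
                :, :, :, ki, kj, :
            ]
    return dxp


def conv2d_transpose(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 2,
                     out_hw: tuple[int, int] | None = None):
    """Transposed convolution (exact adjoint of conv2d).

    x: (N,H,W,Ci), w: (k,k,Co,Ci), output (N, H*stride, W*stride, Co)
    unless ``out_hw`` overrides the spatial size.
    """
    k = w.shape[0]
    n, h, wd, ci = x.shape
    co = w.shape[2]
    oh, ow = out_hw if out_hw is not None else (h * stride, wd * stride)
    ph = same_pad(oh, k, stride)
    pw = same_pad(ow, k, stride)
    xp_shape = (n, oh + ph[0] + ph[1], ow + pw[0] + pw[1], co)
    # adjoint of the strided conv that maps Co channels -> Ci channels
    # with weight w viewed in conv2d layout (k, k, Co, Ci)
    dxp = _scatter_cols(x, w, xp_shape, stride)
    y = dxp[:, ph[0] : xp_shape[1] - ph[1], pw[0] : xp_shape[2] - pw[1], :] + b
    return y


def conv2d_transpose_backward(dy: np.ndarray, x: np.ndarray, w: np.ndarray, stride: int = 2):
    """Gradients of conv2d_transpose wrt input, weight and bias.

    Since the forward map is the adjoint of conv2d, the input gradient
    is a plain strided convolution of dy with the swapped kernel, and
    the weight gradient mirrors conv2d's with the roles of input and
    output exchanged.
    """
    k = w.shape[0]
    ph = same_pad(dy.shape[1], k, stride)
    pw = same_pad(dy.shape[2], k, stride)
    dyp = np.pad(dy, ((0, 0), ph, pw, (0, 0)))
    cols = _cols(dyp, k, stride)  # patches of dy, channels = Co
    dx = np.tensordot(cols, w, axes=([3, 4, 5], [0, 1, 2]))
    # bilinearity: dL/dw = conv2d's weight gradient with input := dy
    # and output gradient := x, landing directly in (k, k, Co, Ci) layout
    dw = np.tensordot(cols, x, axes=([0, 1, 2], [0, 1, 2]))
    db = dy.sum(axis=(0, 1, 2))
    return dx, dw, db


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    q = q.T if rows < cols else q
    return q[:rows, :cols]


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
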