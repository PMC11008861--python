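"""Minimal NumPy building blocks for 1-D convolutional networks.

Activations are kept in (batch, length, channels) layout so that the
im2col'd convolution is a single BLAS matmul per layer in both the forward
and backward pass.  Everything runs in float32; with a fixed seed the
computation is bit-reproducible on a single machine.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _pad_length(x: np.ndarray, pad: int) -> np.ndarray:
    """Zero-pad the length axis of a (B, L, C) tensor on both sides."""
    b, length, c = x.shape
    xp = np.zeros((b, length + 2 * pad, c), dtype=x.dtype)
    xp[:, pad:pad + length, :] = x
    return xp


class Conv1D:
    """Stride-1 'same' 1-D convolution with optional ReLU.

    Evaluated as K shifted batched matmuls,
    y[:, l, :] = sum_k x_padded[:, l+k, :] @ w[k], which keeps every
    operation a large contiguous BLAS call without materialising an
    im2col patch matrix.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for 'same' padding")
        self.c_in, self.c_out, self.kernel, self.relu = c_in, c_out, kernel, relu
        scale = np.sqrt(2.0 / (kernel * c_in))   # He initialisation
        self.w = (rng.standard_normal((kernel, c_in, c_out)) * scale).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._xp: np.ndarray | None = None
        self._pre: np.ndarray | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _, length, _ = x.shape
        k, pad = self.kernel, self.kernel // 2
        xp = _pad_length(x, pad)
        y = np.broadcast_to(self.b, x.shape[:2] + (self.c_out,)).copy()
        for j in range(k):
            y += xp[:, j:j + length, :] @ self.w[j]
        if train:
            self._xp = xp
            self._pre = y if self.relu else None
        if self.relu:
            y = np.maximum(y, 0.0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        _, length, _ = dy.shape
        k, pad = self.kernel, self.kernel // 2
        if self.relu:
            dy = dy * (self._pre > 0)
        self.db = dy.sum(axis=(0, 1))
        dyp = _pad_length(dy, pad)
        dx = np.zeros((dy.shape[0], length, self.c_in), dtype=dy.dtype)
        for j in range(k):
            xs = self._xp[:, j:j + length, :]
            self.dw[j] = np.matmul(xs.transpose(0, 2, 1), dy).sum(axis=0)
            # input gradient: correlation of dy with the flipped kernel
            dx += dyp[:, k - 1 - j:k - 1 - j + length, :] @ self.w[j].T
        return dx

    def params_and_grads(self):
        yield self.w, self.dw
        yield self.b, self.db


def maxpool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Halve the length axis by pairwise max; returns (pooled, argmax)."""
    b, length, c = x.shape
    if length % 2 != 0:
        raise ValueError("length must be even for 2x pooling")
    pairs = x.reshape(b, length // 2, 2, c)
    idx = pairs.argmax(axis=2)
    pooled = np.take_along_axis(pairs, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return pooled, idx

def maxpool2_backward(dy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    b, half, c = dy.shape
    out = np.zeros((b, half, 2, c), dtype=dy.dtype)
    np.put_along_axis(out, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    return out.reshape(b, half * 2, c)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling along the length axis."""
    return np.repeat(x, 2, axis=1)

def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    b, length, c = dy.shape
    return dy.reshape(b, length // 2, 2, c).sum(axis=2)


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for layer in layers
                  for p, _ in layer.params_and_grads()]
        self.v = [np.zeros_like(p) for layer in layers
                  for p, _ in layer.params_and_grads()]

    def step(self) -> None:
        self.t += 1
        bias1 = 1.0 - self.beta1 ** self.t
        bias2 = 1.0 - self.beta2 ** self.t
        i = 0
        for layer in self.layers:
            for p, g in layer.params_and_grads():
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                p -= (self.lr * (self.m[i] / bias1)
                      / (np.sqrt(self.v[i] / bias2) + self.eps)).astype(p.dtype)
                i += 1
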