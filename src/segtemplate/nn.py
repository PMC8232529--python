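"""Minimal CPU neural-network engine for small 3D segmentation networks.

Implements exactly the layers the U-Net needs — 3x3x3 and 1x1x1
convolutions, 2x2x2 max pooling, 3x3x3 stride-2 transposed convolution,
group normalization, ReLU — each as a class with an explicit ``forward``
and analytic ``backward``, plus an Adam optimizer.  Single-sample
(batch-free) layout, channels first: arrays are ``(C, D, H, W)``.

All backward passes are validated against central finite differences in
the test suite; float64 mode exists for those checks, training uses
float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "Deconv3d",
    "MaxPool3d",
    "GroupNorm",
    "ReLU",
    "Adam",
]


class Layer:
    """Base class: layers expose ``params()`` as (name, value, grad) triples."""

    def params(self):
        return []

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0


_OFFSETS3 = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


class Conv3d(Layer):
    """3D convolution, stride 1, kernel 3 (pad 1) or 1 (pad 0).

    Uses a shift-and-matmul im2col: the column matrix is laid out
    ``(fan_in, N)`` and filled by 27 contiguous slice copies from the
    padded input, so the heavy lifting is a single BLAS matmul.  Work
    buffers are reused across calls (shapes are fixed within a training
    run).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, rng=None, dtype=np.float32):
        if kernel not in (1, 3):
            raise ValueError(f"kernel must be 1 or 3, got {kernel}")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel**3
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((c_out, fan_in)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._buffers: dict = {}

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _get_buffers(self, shape, dtype):
        key = (shape, np.dtype(dtype))
        if key not in self._buffers:
            c, d, h, w = shape
            n = d * h * w
            self._buffers.clear()  # keep at most one shape's buffers alive
            self._buffers[key] = (
                np.zeros((c, d + 2, h + 2, w + 2), dtype=dtype),
                np.empty((self.c_in * 27, n), dtype=dtype),
            )
        return self._buffers[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        self._in_shape = x.shape
        n = d * h * w
        if self.kernel == 1:
            cols = x.reshape(c, n)
        else:
            xp, cols = self._get_buffers(x.shape, x.dtype)
            xp[:, 1 : d + 1, 1 : h + 1, 1 : w + 1] = x
            for k, (a, b, cc) in enumerate(_OFFSETS3):
                cols[k * c : (k + 1) * c].reshape(c, d, h, w)[...] = xp[
                    :, a : a + d, b : b + h, cc : cc + w
                ]
        self._cols = cols
        y = self.W @ cols
        y += self.b[:, None]
        return y.reshape(self.c_out, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        dy_mat = dy.reshape(self.c_out, -1)  # (F, N)
        self.dW += dy_mat @ self._cols.T
        self.db += dy_mat.sum(axis=1)
        dcols = self.W.T @ dy_mat  # (fan_in, N)
        if self.kernel == 1:
            return dcols.reshape(c, d, h, w)
        dxp = np.zeros((c, d + 2, h + 2, w + 2), dtype=dy.dtype)
        for k, (a, b, cc) in enumerate(_OFFSETS3):
            dxp[:, a : a + d, b : b + h, cc : cc + w] += dcols[
                k * c : (k + 1) * c
            ].reshape(c, d, h, w)
        return np.ascontiguousarray(dxp[:, 1 : d + 1, 1 : h + 1, 1 : w + 1])


class Deconv3d(Layer):
    """3x3x3 transposed convolution with stride 2 (exact 2x upsampling).

    Realized as zero-stuffing to the doubled grid followed by an ordinary
    3x3x3 convolution; this fixes one of the equivalent kernel-layout
    conventions and keeps the backward pass shared with :class:`Conv3d`.
    """

    def __init__(self, c_in: int, c_out: int, rng=None, dtype=np.float32):
        self.conv = Conv3d(c_in, c_out, kernel=3, rng=rng, dtype=dtype)

    def params(self):
        return self.conv.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        z = np.zeros((c, 2 * d, 2 * h, 2 * w), dtype=x.dtype)
        z[:, ::2, ::2, ::2] = x
        return self.conv.forward(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = self.conv.backward(dy)
        return np.ascontiguousarray(dz[:, ::2, ::2, ::2])


class MaxPool3d(Layer):
    """2x2x2 max pooling (requires even extents)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"max pool requires even extents, got {x.shape}")
        xr = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        g8 = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(g8, self._idx[..., None], dy[..., None], axis=-1)
        return np.ascontiguousarray(
            g8.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )


class GroupNorm(Layer):
    """Group normalization over (channels/groups, spatial), learnable affine."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5, dtype=np.float32):
        groups = min(groups, channels)
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = self.channels
        g = self.groups
        xg = x.reshape(g, -1)
        mu = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        self._sigma = np.sqrt(var + self.eps)
        self._xhat = ((xg - mu) / self._sigma).reshape(x.shape)
        return self._xhat * self.gamma[:, None, None, None] + self.beta[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self.groups
        self.dgamma += (dy * self._xhat).sum(axis=(1, 2, 3))
        self.dbeta += dy.sum(axis=(1, 2, 3))
        dxhat = (dy * self.gamma[:, None, None, None]).reshape(g, -1)
        xhat = self._xhat.reshape(g, -1)
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        dx = (dxhat - m1 - xhat * m2) / self._sigma
        return dx.reshape(dy.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Adam:
    """Adam over the (name, value, grad) parameter triples of a model."""

    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in self.params]
        self.v = [np.zeros_like(p) for _, p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for (name, p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for _, _, g in self.params:
            g[...] = 0.0
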