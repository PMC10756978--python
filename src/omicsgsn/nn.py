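"""Minimal NumPy neural-network layers used by the CNN classifier.

Layers operate on float32 arrays in NCHW layout and expose ``forward`` /
``backward`` plus flat ``params`` / ``grads`` lists consumed by the Adam
optimizer.  Convolution is 'valid' (no padding), implemented as im2col +
matrix multiply; max-pool backward splits the gradient equally among tied
maxima within a window.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """(C, H, W) -> (C, H, W) after this layer."""
        return in_shape


def _windows(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Strided view (N, C, Ho, Wo, kh, kw) of kh x kw windows."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(n, c, ho, wo, kh, kw),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )


class Conv2D(Layer):
    """3x3 (or kxk) valid convolution followed by ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True) -> None:
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel * kernel
        # He initialization, appropriate for the ReLU that follows.
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.relu = relu
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if h < self.k or w < self.k:
            raise ValueError(
                f"Conv2D({self.cout}x{self.k}x{self.k}): input {h}x{w} smaller than kernel"
            )
        return (self.cout, h - self.k + 1, w - self.k + 1)

    def forward(self, x, training, rng=None):
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, c, h, w = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        cols = _windows(x, k, k, 1).transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.w.T + self.b
        out = out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        self._cols, self._in_shape = cols, (n, c, h, w)
        if self.relu:
            self._pre_relu_mask = out > 0
            out = out * self._pre_relu_mask
        return np.ascontiguousarray(out)

    def backward(self, dout):
        if self.relu:
            dout = dout * self._pre_relu_mask
        n, c, h, w = self._in_shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.grads[0][...] = dmat.T @ self._cols
        self.grads[1][...] = dmat.sum(axis=0)
        dcols = (dmat @ self.w).reshape(n, ho, wo, c, k, k)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di:di + ho, dj:dj + wo] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dx


class MaxPool2D(Layer):
    def __init__(self, size: int = 2, stride: int = 1) -> None:
        super().__init__()
        self.size, self.stride = size, stride

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if h < self.size or w < self.size:
            raise ValueError(f"MaxPool2D({self.size}, stride {self.stride}): input {h}x{w} too small")
        return (c, (h - self.size) // self.stride + 1, (w - self.size) // self.stride + 1)

    def forward(self, x, training, rng=None):
        x = np.ascontiguousarray(x, dtype=np.float32)
        win = _windows(x, self.size, self.size, self.stride)
        out = win.max(axis=(4, 5))
        self._x, self._out = x, out
        return out

    def backward(self, dout):
        x, out = self._x, self._out
        n, c, ho, wo = out.shape
        k, s = self.size, self.stride
        # Split the gradient equally among tied maxima within each window.
        count = np.zeros_like(out)
        for di in range(k):
            for dj in range(k):
                sl = x[:, :, di:di + (ho - 1) * s + 1:s, dj:dj + (wo - 1) * s + 1:s]
                count += (sl == out)
        share = dout / count
        dx = np.zeros_like(x)
        for di in range(k):
            for dj in range(k):
                sl = x[:, :, di:di + (ho - 1) * s + 1:s, dj:dj + (wo - 1) * s + 1:s]
                dx[:, :, di:di + (ho - 1) * s + 1:s, dj:dj + (wo - 1) * s + 1:s] += share * (sl == out)
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, training, rng=None):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if training:
            self._xhat, self._inv_std = xhat, inv_std
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv_std = self._xhat, self._inv_std
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads[0][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an RNG"
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c * h * w, 1, 1)

    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    eps = 1e-12
    return float(-(onehot * np.log(probs + eps)).sum() / probs.shape[0])


class Adam:
    """Adaptive-moment estimation over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
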