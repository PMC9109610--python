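"""Minimal 2-D convolutional network engine (numpy, CPU).

Implements exactly the pieces the ventilation U-net needs: 3x3/1x1
convolutions (im2col + BLAS matmul), ReLU, 2x2 max pooling, 2x2 nearest
upsampling, channel concatenation, inverted dropout, he-normal
initialization, mean-squared-error loss and RMSprop — with full backward
passes.  Everything is float32 and deterministic given the seeds supplied.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Dropout",
    "RMSprop",
    "mse_loss",
]


def he_normal(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) with 'same' zero padding, stride 1."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # view: (N, C, H, W, k, k) -> (N, C, k, k, H*W)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape: tuple[int, ...], k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add column gradients back to the image."""
    n, c, h, w = x_shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
    return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Conv2D:
    """k x k convolution, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.c_in = c_in
        self.W = he_normal(rng, c_in * k * k, (c_out, c_in * k * k))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = None
        self.db = None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            out = np.einsum("oc,nchw->nohw", self.W.reshape(-1, c), x, optimize=True)
            self._cache = (x, None)
        else:
            cols = _im2col(x, self.k)
            out = (self.W @ cols).reshape(n, -1, h, w)
            self._cache = (x.shape, cols)
        return out + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, co, h, w = dy.shape
        self.db = dy.sum(axis=(0, 2, 3))
        if self.k == 1:
            x, _ = self._cache
            self.dW = np.einsum("nohw,nchw->oc", dy, x, optimize=True).reshape(self.W.shape)
            return np.einsum("oc,nohw->nchw", self.W.reshape(co, -1), dy, optimize=True)
        x_shape, cols = self._cache
        dy_flat = np.ascontiguousarray(dy.reshape(n, co, h * w))
        self.dW = np.matmul(dy_flat, cols.transpose(0, 2, 1)).sum(axis=0)
        dcols = np.matmul(self.W.T[None], dy_flat)
        return _col2im(dcols, x_shape, self.k)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2:
    """2x2 max pooling with stride 2."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        dflat = np.zeros((n, c, h2, w2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(self._in_shape)


class Upsample2:
    """2x nearest-neighbor upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout:
    """Inverted dropout; identity at inference or rate 0."""

    def __init__(self, rate: float):
        self.rate = float(rate)
        self.rng = np.random.default_rng(0)
        self._mask = None

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class RMSprop:
    """Keras-style RMSprop: cache = rho*cache + (1-rho)*g^2."""

    def __init__(self, layers: list, lr: float = 1e-4, rho: float = 0.9, eps: float = 1e-7):
        self.layers = [l for l in layers if isinstance(l, Conv2D)]
        self.lr = float(lr)
        self.rho = rho
        self.eps = eps
        self._cache = {id(l): (np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers}

    def step(self) -> None:
        for layer in self.layers:
            cw, cb = self._cache[id(layer)]
            cw *= self.rho
            cw += (1 - self.rho) * layer.dW.astype(np.float32) ** 2
            cb *= self.rho
            cb += (1 - self.rho) * layer.db.astype(np.float32) ** 2
            layer.W -= self.lr * layer.dW / (np.sqrt(cw) + self.eps)
            layer.b -= self.lr * layer.db / (np.sqrt(cb) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to pred."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff
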