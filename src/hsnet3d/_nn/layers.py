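"""Layers with hand-written forward/backward passes.

Volumes are channels-first: (N, C, D, H, W).  Convolution is 3x3x3,
stride 1, same padding, computed by row-vectorized compiled kernels; the
backward data pass is the same convolution with the kernel flipped and
the channel axes swapped.  Each layer caches what its backward pass
needs during forward; layers are used strictly sequentially.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as k


class Layer:
    """Base: trainable ``params``/``grads`` and non-trainable ``state`` dicts."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def state(self) -> dict:
        return {}


class Conv3D(Layer):
    """3x3x3 same-padded convolution; weights (3, 3, 3, cin, cout)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = 27 * cin
        self.W = (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(3, 3, 3, cin, cout))
                  .astype(np.float32))
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.cin, self.cout = cin, cout
        self._xp = None
        self._first_layer = False  # first layer skips the (unused) data gradient

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    @staticmethod
    def _pad(x):
        return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, _, d, h, w = x.shape
        xp = self._pad(x)
        self._xp = xp if train else None
        out = np.empty((n, self.cout, d, h, w), dtype=np.float32)
        k.conv3d_forward(xp, self.W, self.b, out)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        self.dW[:] = 0.0
        self.db[:] = 0.0
        k.conv3d_weight_grad(self._xp, dy, self.dW, self.db)
        if self._first_layer:
            return None
        # transposed convolution: flipped kernel, channel axes swapped
        kt = np.ascontiguousarray(
            self.W[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3))
        dx = np.empty((dy.shape[0], self.cin) + dy.shape[2:], dtype=np.float32)
        k.conv3d_forward(self._pad(dy), kt, np.zeros(self.cin, np.float32), dx)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None
        # accumulation mode: sums of batch moments for SWA statistic refresh
        self._accum = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def start_accumulation(self):
        self._accum = [np.zeros_like(self.running_mean),
                       np.zeros_like(self.running_var), 0]

    def finish_accumulation(self):
        s_mean, s_var, count = self._accum
        if count > 0:
            self.running_mean[:] = s_mean / count
            self.running_var[:] = s_var / count
        self._accum = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean, var = k.bn_moments(x)
            if self._accum is not None:
                self._accum[0] += mean
                self._accum[1] += var
                self._accum[2] += 1
            else:
                mom = self.momentum
                self.running_mean[:] = mom * self.running_mean + (1 - mom) * mean
                self.running_var[:] = mom * self.running_var + (1 - mom) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        scale = self.gamma * inv_std
        shift = self.beta - mean * scale
        if train:
            self._cache = (x, mean.astype(np.float32), inv_std)
        return k.scale_shift(x, scale, shift, np.empty_like(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mean, inv_std = self._cache
        m = float(x.size / x.shape[1])
        s_dy, s_dyx = k.bn_backward_reductions(x, dy)
        self.dbeta[:] = s_dy
        self.dgamma[:] = inv_std * (s_dyx - mean * s_dy)
        a = self.gamma * inv_std
        b = -(self.gamma * self.dgamma) * inv_std * inv_std / np.float32(m)
        c = -a * self.dbeta / np.float32(m) - mean * b
        return k.affine_combine(dy, x, a, b, c, np.empty_like(dy))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.ndim == 5:
            out = np.empty_like(x)
            k.relu_forward(x, out)
        else:
            out = np.maximum(x, 0.0)
        if train:
            self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if dy.ndim == 5:
            dx = np.empty_like(dy)
            k.relu_backward(np.ascontiguousarray(dy), self._out, dx)
            return dx
        return dy * (self._out > 0)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32)
        mask /= keep
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2.

    The gradient goes to the argmax voxel; on ties the earliest corner
    (lowest z, y, x offset) wins.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        y = np.empty((n, c, d // 2, h // 2, w // 2), dtype=np.float32)
        idx = np.empty(y.shape, dtype=np.int8)
        k.maxpool_forward(x, y, idx)
        if train:
            self._idx = idx
            self._x_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._x_shape, dtype=np.float32)
        k.maxpool_backward(np.ascontiguousarray(dy), self._idx, dx)
        return dx


class AvgPool3D(Layer):
    """2x2x2 average pooling, stride 2.

    Preserves mean intensity information that max pooling discards —
    preferable when heads must estimate contrast or density levels
    rather than detect peaks.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        if train:
            self._x_shape = x.shape
        return xr.mean(axis=(3, 5, 7), dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = (dy / 8.0).astype(np.float32)
        for axis in (2, 3, 4):
            g = np.repeat(g, 2, axis=axis)
        return np.ascontiguousarray(g)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.W = (rng.normal(0.0, np.sqrt(2.0 / fin), size=(fin, fout))
                  .astype(np.float32))
        self.b = np.zeros(fout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return (dy @ self.W.T).astype(np.float32)
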