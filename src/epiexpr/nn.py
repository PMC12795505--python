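"""A compact, deterministic 1-D convolutional network in numpy.

Implements exactly the layer set the expression models need — batch
normalization, ReLU, same-padded 1-D convolution, inverted dropout,
max-pooling, dense layers — with reverse-mode gradients and an Adam
optimizer.  All randomness (initialization, dropout masks, batch shuffling)
flows from a single ``numpy.random.Generator``, so training is bit-
reproducible given a seed on a fixed BLAS.

Tensors are (batch, channels, width) for convolutional layers and
(batch, features) after flattening.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameters live in ``params``; gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution, (B, C, W) → (B, F, W)."""

    def __init__(self, in_channels: int, filters: int, width: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if width % 2 == 0:
            raise ValueError("kernel width must be odd for same padding")
        self.c, self.f, self.k = in_channels, filters, width
        fan_in = in_channels * width
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, filters))
        self.params["b"] = np.zeros(filters)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # col[b, w, c, t] = xp[b, c, w + t]
        col = sliding_window_view(xp, self.k, axis=2).transpose(0, 2, 1, 3)
        self._col = col.reshape(b, w, c * self.k)
        y = self._col @ self.params["W"] + self.params["b"]
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, f, w = dy.shape
        dyt = dy.transpose(0, 2, 1)                       # (B, W, F)
        flat_col = self._col.reshape(-1, self.c * self.k)
        self.grads["W"] = flat_col.T @ dyt.reshape(-1, f)
        self.grads["b"] = dyt.sum(axis=(0, 1))
        dcol = (dyt @ self.params["W"].T).reshape(b, w, self.c, self.k)
        p = self.k // 2
        dxp = np.zeros((b, self.c, w + 2 * p))
        for t in range(self.k):
            dxp[:, :, t:t + w] += dcol[:, :, :, t].transpose(0, 2, 1)
        return dxp[:, :, p:p + w]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, width)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        return self.params["gamma"][None, :, None] * self._xhat + \
            self.params["beta"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        n = dy.shape[0] * dy.shape[2]
        g = self.params["gamma"][None, :, None]
        dxhat = dy * g
        mean_d = dxhat.mean(axis=(0, 2), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return (dxhat - mean_d - xhat * mean_dx) / self._std


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability {p} outside [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder column is dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, w = x.shape
        wo = w // self.size
        self._in_shape = x.shape
        xr = x[:, :, :wo * self.size].reshape(b, c, wo, self.size)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, wo = dy.shape
        dxr = np.zeros((b, c, wo, self.size))
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, :wo * self.size] = dxr.reshape(b, c, wo * self.size)
        return dx


class AvgPool1D(Layer):
    """Non-overlapping mean pooling; a trailing remainder column is dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, w = x.shape
        wo = w // self.size
        self._in_shape = x.shape
        return x[:, :, :wo * self.size].reshape(b, c, wo, self.size).mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, wo = dy.shape
        dx = np.zeros(self._in_shape)
        dx[:, :, :wo * self.size] = np.repeat(dy / self.size, self.size, axis=2)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{i}.{name}", layer


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(layer.params[k.split(".", 1)[1]])
                  for k, layer in model.parameters()}
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for key, layer in self.model.parameters():
            name = key.split(".", 1)[1]
            g = layer.grads[name]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = pred - y
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
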