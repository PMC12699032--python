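"""Minimal CNN building blocks on numpy: im2col convolutions, dense layers,
ReLU, an RMSE loss, and decoupled-weight-decay Adam (AdamW).

Everything runs in float32 and is deterministic given the initialization
generator, which is what the training harness needs for reproducible desk-
scale experiments on a single CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-style convolution via im2col + matmul; He-normal init."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = (rng.standard_normal((c_out, c_in, kernel, kernel)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _cols(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        # [N, C, Ho, Wo, k, k]
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        return win

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = self._cols(xp)
        N, C, Ho, Wo, k, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        self._cache = (x.shape, cols, (N, Ho, Wo))
        return out.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols, (N, Ho, Wo) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        c_out = self.W.shape[0]
        dy_f = dy.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, c_out)
        self.grads[0][...] = (dy_f.T @ cols).reshape(self.W.shape)
        self.grads[1][...] = dy_f.sum(axis=0)
        dcols = dy_f @ self.W.reshape(c_out, -1)           # [NHoWo, Ckk]
        C = x_shape[1]
        dwin = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        Hp, Wp = x_shape[2] + 2 * p, x_shape[3] + 2 * p
        dxp = np.zeros((N, C, Hp, Wp), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += dwin[:, :, :, :, ki, kj]
        return dxp[:, :, p:Hp - p, p:Wp - p] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


def rmse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Root-mean-square error over all outputs and its gradient w.r.t. pred."""
    diff = (pred - target).astype(np.float32)
    mse = float(np.mean(diff ** 2))
    loss = float(np.sqrt(mse))
    if loss < 1e-12:
        return loss, np.zeros_like(diff)
    return loss, diff / (diff.size * loss)


class AdamW:
    """Adam with decoupled weight decay (weight decay skips biases/1-D params)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.99), eps: float = 1e-8,
                 weight_decay: float = 1e-3) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if p.ndim > 1 and self.weight_decay:
                update = update + self.weight_decay * p
            p -= self.lr * update
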