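"""Minimal numpy neural-network engine for the force regression model.

Implements exactly the layers the force network needs — a time-distributed
2-D convolution, LSTM layers returning full sequences, a per-step dense
readout — with manual backpropagation and an Adam optimizer.  Everything is
float32 and fully deterministic given the construction seed (single-threaded
numpy; no dropout, no nondeterministic kernels).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(DTYPE)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    size = max(rows, cols)
    q, _ = np.linalg.qr(rng.standard_normal((size, size)))
    return q[:rows, :cols].astype(DTYPE)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class TimeDistributedConv2D(Layer):
    """Same-padding 2-D convolution + ReLU applied independently per time step.

    Input (B, T, H, W, C_in) -> output (B, T, H, W, filters).
    """

    def __init__(self, c_in: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel
        fan_in = kh * kw * c_in
        self.kernel = kernel
        self.w = _glorot(rng, (fan_in, filters), fan_in, filters)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        b_, t_, h_, w_, c = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw), (0, 0)))
        # patches: (B, T, H, W, C, kh, kw) -> (..., kh, kw, C)
        patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))
        patches = np.ascontiguousarray(np.moveaxis(patches, 4, 6))
        self._patches = patches.reshape(-1, kh * kw * c)
        self._in_shape = x.shape
        pre = self._patches @ self.w + self.b
        self._mask = pre > 0
        out = np.where(self._mask, pre, 0.0)
        return out.reshape(b_, t_, h_, w_, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        b_, t_, h_, w_, c = self._in_shape
        dflat = dy.reshape(-1, dy.shape[-1]) * self._mask
        self.grads[0][...] = self._patches.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dpatches = (dflat @ self.w.T).reshape(b_, t_, h_, w_, kh, kw, c)
        dxp = np.zeros((b_, t_, h_ + 2 * ph, w_ + 2 * pw, c), dtype=DTYPE)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + h_, j:j + w_, :] += dpatches[:, :, :, :, i, j, :]
        return dxp[:, :, ph:ph + h_, pw:pw + w_, :]


class Flatten(Layer):
    """(B, T, H, W, C) -> (B, T, H*W*C)."""

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        b_, t_ = x.shape[:2]
        return x.reshape(b_, t_, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Standard LSTM returning the full hidden sequence (B, T, units).

    Gate order i, f, g, o; forget-gate bias initialized to 1.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.wx = _glorot(rng, (d_in, 4 * units), d_in, 4 * units)
        self.wh = _orthogonal(rng, units, 4 * units)
        self.b = np.zeros(4 * units, dtype=DTYPE)
        self.b[units:2 * units] = 1.0
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b_, t_, _ = x.shape
        u = self.units
        h = np.zeros((b_, t_ + 1, u), dtype=DTYPE)
        c = np.zeros((b_, t_ + 1, u), dtype=DTYPE)
        gates = np.zeros((b_, t_, 4 * u), dtype=DTYPE)
        xw = x @ self.wx  # precompute input contribution for all steps
        for t in range(t_):
            pre = xw[:, t] + h[:, t] @ self.wh + self.b
            i = _sigmoid(pre[:, :u])
            f = _sigmoid(pre[:, u:2 * u])
            g = np.tanh(pre[:, 2 * u:3 * u])
            o = _sigmoid(pre[:, 3 * u:])
            c[:, t + 1] = f * c[:, t] + i * g
            h[:, t + 1] = o * np.tanh(c[:, t + 1])
            gates[:, t] = np.concatenate([i, f, g, o], axis=1)
        self._cache = (x, h, c, gates)
        return h[:, 1:]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, h, c, gates = self._cache
        b_, t_, _ = x.shape
        u = self.units
        dwx, dwh, db = (np.zeros_like(self.wx), np.zeros_like(self.wh),
                        np.zeros_like(self.b))
        dx = np.zeros_like(x)
        dh_next = np.zeros((b_, u), dtype=DTYPE)
        dc_next = np.zeros((b_, u), dtype=DTYPE)
        for t in range(t_ - 1, -1, -1):
            i = gates[:, t, :u]
            f = gates[:, t, u:2 * u]
            g = gates[:, t, 2 * u:3 * u]
            o = gates[:, t, 3 * u:]
            tanh_c = np.tanh(c[:, t + 1])
            dh = dy[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c[:, t]
            dg = dc * i
            dpre = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ], axis=1)
            dwx += x[:, t].T @ dpre
            dwh += h[:, t].T @ dpre
            db += dpre.sum(axis=0)
            dx[:, t] = dpre @ self.wx.T
            dh_next = dpre @ self.wh.T
            dc_next = dc * f
        self.grads[0][...] = dwx
        self.grads[1][...] = dwh
        self.grads[2][...] = db
        return dx


class TimeDistributedDense(Layer):
    """Per-step linear map (B, T, D) -> (B, T, units)."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.w = _glorot(rng, (d_in, units), d_in, units)
        self.b = np.zeros(units, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("btd,btu->du", self._x, dy)
        self.grads[1][...] = dy.sum(axis=(0, 1))
        return dy @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def rmsd_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-window RMSD (percent) averaged over the batch, with its gradient.

    ``pred``/``target`` are (B, T); the loss for each window is
    sqrt(mean_t (pred - target)^2) * 100 and the batch loss is their mean.
    """
    pred = pred.astype(np.float64)
    diff = pred - target
    per_window = np.sqrt(np.mean(diff**2, axis=1))
    loss = float(per_window.mean() * 100.0)
    b_, t_ = pred.shape
    safe = np.where(per_window > 0, per_window, 1.0)
    grad = 100.0 * diff / (t_ * safe[:, None]) / b_
    grad[per_window == 0] = 0.0
    return loss, grad.astype(DTYPE)
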