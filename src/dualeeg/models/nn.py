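"""Minimal numpy neural-network layers with exact backpropagation.

Implements just the pieces the classifiers need — dense, 2-D convolution
(same padding, stride 1), batch normalization, ReLU, dropout, flatten,
(bi)directional LSTM — plus softmax cross-entropy and an Adam optimizer.
Every layer's backward pass is verified against numeric differentiation in
the test suite.

Shapes: dense (B, F); conv (B, H, W, C); sequences (B, T, F).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "ReLU", "Dropout", "Flatten", "Conv2D", "BatchNorm", "LSTM",
    "BiLSTM", "Sequential", "Adam", "softmax", "softmax_cross_entropy",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Layer:
    """Base layer: forward/backward plus flat parameter/gradient lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, 'same' zero padding.

    Input (B, H, W, C_in) -> output (B, H, W, C_out).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3):
        k = kernel
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.w = _glorot(rng, (k, k, c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        k = self.k
        p = k // 2
        self._xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        b_, h, w, _ = x.shape
        out = np.tile(self.b, (b_, h, w, 1))
        for di in range(k):
            for dj in range(k):
                patch = self._xpad[:, di:di + h, dj:dj + w, :]
                out += patch @ self.w[di, dj]
        return out

    def backward(self, dout):
        k = self.k
        p = k // 2
        b_, h, w, _ = dout.shape
        dxpad = np.zeros_like(self._xpad)
        for di in range(k):
            for dj in range(k):
                patch = self._xpad[:, di:di + h, dj:dj + w, :]
                self.dw[di, dj] = np.einsum("bhwc,bhwo->co", patch, dout)
                dxpad[:, di:di + h, dj:dj + w, :] += dout @ self.w[di, dj].T
        self.db[...] = dout.sum(axis=(0, 1, 2))
        return dxpad[:, p:p + h, p:p + w, :]


class BatchNorm(Layer):
    """Normalize over every axis except the last (features/channels).

    Works for dense (B, F), sequence (B, T, F) and conv (B, H, W, C)
    inputs alike; keeps running statistics for inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros(n_features)
        self.dbeta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        axes = self._axes
        self.dgamma[...] = (dout * self._xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        if not self._training:
            return dout * self.gamma / self._std
        n = self._n
        dxhat = dout * self.gamma
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(Layer):
    """Single-direction LSTM over (B, T, F) input.

    Returns the full hidden sequence (B, T, H) when ``return_sequences``
    else the final hidden state (B, H).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        h = n_hidden
        self.wx = _glorot(rng, (n_in, 4 * h), n_in, 4 * h)
        self.wh = _glorot(rng, (h, 4 * h), h, 4 * h)
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = 1.0  # forget-gate bias
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)
        self.h = h
        self.return_sequences = return_sequences

    def params(self):
        return [self.wx, self.wh, self.b]

    def grads(self):
        return [self.dwx, self.dwh, self.db]

    def forward(self, x, training=False):
        b_, t, _ = x.shape
        h = self.h
        self._x = x
        self._cache = []
        h_t = np.zeros((b_, h))
        c_t = np.zeros((b_, h))
        hs = np.empty((b_, t, h))
        for step in range(t):
            z = x[:, step, :] @ self.wx + h_t @ self.wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tanh_c = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tanh_c
            self._cache.append((i, f, g, o, c_prev, tanh_c, h_prev))
            hs[:, step, :] = h_t
        self._hs = hs
        return hs if self.return_sequences else h_t

    def backward(self, dout):
        x = self._x
        b_, t, _ = x.shape
        h = self.h
        self.dwx[...] = 0.0
        self.dwh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((b_, h))
        dc_next = np.zeros((b_, h))
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = self._cache[step]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout[:, step, :]
            elif step == t - 1:
                dh += dout
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g**2),
                do * o * (1 - o),
            ], axis=1)
            self.dwx += x[:, step, :].T @ dz
            self.dwh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Forward + backward LSTM; outputs concatenated on the feature axis.

    With ``return_sequences`` the output is (B, T, 2H) (backward pass
    re-reversed so step t aligns); otherwise (B, 2H) from the two final
    states.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        self.fwd = LSTM(n_in, n_hidden, rng, return_sequences=return_sequences)
        self.bwd = LSTM(n_in, n_hidden, rng, return_sequences=return_sequences)
        self.return_sequences = return_sequences
        self.h = n_hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def grads(self):
        return self.fwd.grads() + self.bwd.grads()

    def forward(self, x, training=False):
        out_f = self.fwd.forward(x, training)
        out_b = self.bwd.forward(x[:, ::-1, :], training)
        if self.return_sequences:
            out_b = out_b[:, ::-1, :]
        return np.concatenate([out_f, out_b], axis=-1)

    def backward(self, dout):
        h = self.h
        d_f, d_b = dout[..., :h], dout[..., h:]
        if self.return_sequences:
            d_b = d_b[:, ::-1, :]
        dx_f = self.fwd.backward(np.ascontiguousarray(d_f))
        dx_b = self.bwd.backward(np.ascontiguousarray(d_b))
        return dx_f + dx_b[:, ::-1, :]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam with externally controlled learning rate (for step decay)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
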