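"""Minimal numpy neural-network engine used by the window classifiers.

Implements exactly the layers the architectures in :mod:`splitbench.models`
need — dense, 1-D convolution (stride 1, no padding), max-pooling, dropout,
LSTM and GRU — with hand-written reverse-mode gradients and an Adam optimizer.
The engine is deliberately small: single precision by default, CPU only,
deterministic given a seed.

Conventions
-----------
* Sequence inputs are ``(batch, length, channels)`` arrays.
* Convolution kernels span the full channel depth (a "9 x 21" kernel is a
  length-9 window over all 21 channels), so output length is ``L - k + 1``.
* Max-pooling of size p truncates a trailing remainder (floor division).
* The output neuron produces a raw logit; the sigmoid lives in the loss /
  scoring functions for numerical stability.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.astype(logits.dtype)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Dense(Layer):
    """Affine map on the last axis (used for FC layers and the WE map)."""

    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (din, dout), din, dout, dtype)
        self.params["b"] = np.zeros(dout, dtype=dtype)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv1D(Layer):
    """1-D convolution, stride 1, no padding, full channel depth."""

    def __init__(self, kernel: int, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.kernel = kernel
        self.cin = cin
        fan_in = kernel * cin
        self.params["W"] = glorot_uniform(rng, (fan_in, cout), fan_in, cout, dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        b, length, cin = x.shape
        k = self.kernel
        lout = length - k + 1
        # im2col: (B, Lout, k, Cin) -> (B*Lout, k*Cin)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(b * lout, k * cin)
        self._col, self._xshape = col, x.shape
        y = col @ self.params["W"] + self.params["b"]
        return y.reshape(b, lout, -1)

    def backward(self, dy):
        b, lout, cout = dy.shape
        k, cin = self.kernel, self.cin
        dy2 = dy.reshape(b * lout, cout)
        self.grads["W"] += self._col.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        dcol = (dy2 @ self.params["W"].T).reshape(b, lout, k, cin)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        for t in range(k):  # col2im scatter-add, k is small
            dx[:, t:t + lout, :] += dcol[:, :, t, :]
        return dx


class MaxPool1D(Layer):
    """Max-pooling over the length axis; trailing remainder is dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train=False, rng=None):
        b, length, c = x.shape
        p = self.size
        lout = length // p
        xt = x[:, :lout * p].reshape(b, lout, p, c)
        self._xshape = x.shape
        if p == 2:  # fast path: a single comparison instead of argmax
            first, second = xt[:, :, 0], xt[:, :, 1]
            self._take_second = second > first
            self._idx = None
            return np.where(self._take_second, second, first)
        self._idx = xt.argmax(axis=2)
        return np.take_along_axis(xt, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        b, lout, c = dy.shape
        p = self.size
        dxt = np.zeros((b, lout, p, c), dtype=dy.dtype)
        if self._idx is None:
            dxt[:, :, 1] = dy * self._take_second
            dxt[:, :, 0] = dy - dxt[:, :, 1]
        else:
            np.put_along_axis(dxt, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        dx[:, :lout * p] = dxt.reshape(b, lout * p, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class LastStep(Layer):
    """Keep only the final timestep of a (B, T, H) sequence."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=dy.dtype)
        dx[:, -1, :] = dy
        return dx


class LSTM(Layer):
    """Single LSTM sublayer returning the full hidden sequence (B, T, H).

    Gate order in the packed weight matrices is (input, forget, cell, output).
    Initial hidden and cell states are zero.
    """

    def __init__(self, din: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        self.params["Wx"] = glorot_uniform(rng, (din, 4 * hidden), din, hidden, dtype)
        self.params["Wh"] = glorot_uniform(rng, (hidden, 4 * hidden), hidden, hidden, dtype)
        self.params["b"] = np.zeros(4 * hidden, dtype=dtype)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        b, t_len, _ = x.shape
        hdim = self.hidden
        Wx, Wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((b, hdim), dtype=x.dtype)
        c = np.zeros((b, hdim), dtype=x.dtype)
        xa = x @ Wx + bias  # precompute input contributions for all t
        out = np.empty((b, t_len, hdim), dtype=x.dtype)
        cache = []
        for t in range(t_len):
            a = xa[:, t] + h @ Wh
            i = sigmoid(a[:, :hdim]).astype(x.dtype)
            f = sigmoid(a[:, hdim:2 * hdim]).astype(x.dtype)
            g = np.tanh(a[:, 2 * hdim:3 * hdim])
            o = sigmoid(a[:, 3 * hdim:]).astype(x.dtype)
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h
        self._cache, self._x = cache, x
        return out

    def backward(self, dy):
        x = self._x
        b, t_len, _ = x.shape
        hdim = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx, dWh, db = self.grads["Wx"], self.grads["Wh"], self.grads["b"]
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, hdim), dtype=x.dtype)
        dc_next = np.zeros((b, hdim), dtype=x.dtype)
        for t in reversed(range(t_len)):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dy[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ Wx.T
            dh_next = da @ Wh.T
            dc_next = dc * f
        return dx


class GRU(Layer):
    """Single GRU sublayer returning the full hidden sequence (B, T, H).

    Gate order is (update z, reset r, candidate n); the reset gate multiplies
    the hidden contribution after the matrix product, i.e.
    ``n = tanh(x Wxn + r * (h Whn))``.
    """

    def __init__(self, din: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        self.params["Wx"] = glorot_uniform(rng, (din, 3 * hidden), din, hidden, dtype)
        self.params["Wh"] = glorot_uniform(rng, (hidden, 3 * hidden), hidden, hidden, dtype)
        self.params["b"] = np.zeros(3 * hidden, dtype=dtype)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        b, t_len, _ = x.shape
        hdim = self.hidden
        Wx, Wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((b, hdim), dtype=x.dtype)
        xa = x @ Wx + bias
        out = np.empty((b, t_len, hdim), dtype=x.dtype)
        cache = []
        for t in range(t_len):
            ah = h @ Wh
            z = sigmoid(xa[:, t, :hdim] + ah[:, :hdim]).astype(x.dtype)
            r = sigmoid(xa[:, t, hdim:2 * hdim] + ah[:, hdim:2 * hdim]).astype(x.dtype)
            ahn = ah[:, 2 * hdim:]
            n = np.tanh(xa[:, t, 2 * hdim:] + r * ahn)
            h_new = (1.0 - z) * n + z * h
            cache.append((h, z, r, n, ahn))
            h = h_new
            out[:, t] = h
        self._cache, self._x = cache, x
        return out

    def backward(self, dy):
        x = self._x
        b, t_len, _ = x.shape
        hdim = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx, dWh, db = self.grads["Wx"], self.grads["Wh"], self.grads["b"]
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, hdim), dtype=x.dtype)
        for t in reversed(range(t_len)):
            h_prev, z, r, n, ahn = self._cache[t]
            dh = dy[:, t] + dh_next
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dan = dn * (1.0 - n * n)          # pre-tanh candidate
            dr = dan * ahn
            da_x = np.concatenate(
                [dz * z * (1 - z), dr * r * (1 - r), dan], axis=1
            )
            da_h = np.concatenate(
                [dz * z * (1 - z), dr * r * (1 - r), dan * r], axis=1
            )
            dWx += x[:, t].T @ da_x
            dWh += h_prev.T @ da_h
            db += da_x.sum(axis=0)
            dx[:, t] = da_x @ Wx.T
            dh_next = da_h @ Wh.T + dh * z
        return dx


class Network:
    """A plain feed-forward stack of layers ending in a single raw logit."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x[:, 0] if x.ndim == 2 and x.shape[1] == 1 else x

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits[:, None] if dlogits.ndim == 1 else dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def parameters(self) -> list[tuple[dict, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def get_state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self.layers, state, strict=True):
            for k, v in params.items():
                layer.params[k][...] = v


class Adam:
    """Adam with the canonical defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, m, v in zip(self.net.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
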