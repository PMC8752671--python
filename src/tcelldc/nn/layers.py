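"""Minimal NumPy layer library with forward/backward passes.

Only what the CNN-LSTM video classifier needs: 3x3 same-padded
convolutions, batch normalization, overlapping max pooling, dense layers
and an LSTM with input/recurrent dropout.  Every layer caches what its
backward pass needs; parameter gradients land in ``layer.grads``.
All computation is float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "BatchNorm",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "LSTM",
]


def _glorot(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: parameter dict, gradient dict, capture hooks."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.capture = False       # keep last_output / last_output_grad
        self.last_output = None
        self.last_output_grad = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _maybe_capture_out(self, out):
        if self.capture:
            self.last_output = out
        return out

    def _maybe_capture_grad(self, gout):
        if self.capture:
            self.last_output_grad = gout


class Conv2D(Layer):
    """3x3 convolution with 'same' zero padding, NHWC layout, via im2col."""

    def __init__(self, name, c_in, c_out, rng, kernel=3):
        super().__init__(name)
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        self.params["W"] = _glorot(rng, fan_in, fan_out, (fan_in, c_out))
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        cols = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        flat = cols.reshape(n * h * w, self.k * self.k * self.c_in)
        out = flat @ self.params["W"] + self.params["b"]
        out = out.reshape(n, h, w, self.c_out)
        self._cache = (flat, x.shape)
        return self._maybe_capture_out(out)

    def backward(self, gout):
        self._maybe_capture_grad(gout)
        flat, xshape = self._cache
        n, h, w, _ = xshape
        gflat = gout.reshape(n * h * w, self.c_out)
        self.grads["W"] = flat.T @ gflat
        self.grads["b"] = gflat.sum(axis=0)
        dcols = (gflat @ self.params["W"].T).reshape(
            n, h, w, self.k, self.k, self.c_in
        )
        pad = self.k // 2
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, self.c_in), dtype=np.float32)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, ki : ki + h, kj : kj + w, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, pad : pad + h, pad : pad + w, :]


class ReLU(Layer):
    def __init__(self, name):
        super().__init__(name)

    def forward(self, x, train=False):
        self._mask = x > 0
        return self._maybe_capture_out(np.where(self._mask, x, 0.0))

    def backward(self, gout):
        self._maybe_capture_grad(gout)
        return np.where(self._mask, gout, 0.0)


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, name, channels, momentum=0.99, eps=1e-3):
        super().__init__(name)
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        out = self.params["gamma"] * xhat + self.params["beta"]
        self._cache = (xhat, inv, train, x.shape, axes)
        return self._maybe_capture_out(out.astype(np.float32))

    def backward(self, gout):
        self._maybe_capture_grad(gout)
        xhat, inv, train, xshape, axes = self._cache
        self.grads["gamma"] = (gout * xhat).sum(axis=axes)
        self.grads["beta"] = gout.sum(axis=axes)
        g = self.params["gamma"]
        if not train:
            return (gout * g * inv).astype(np.float32)
        m = float(np.prod([xshape[a] for a in axes]))
        dxhat = gout * g
        dx = (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - xhat * (dxhat * xhat).sum(axis=axes)
            )
        )
        return dx.astype(np.float32)


class MaxPool2D(Layer):
    """pool x pool max pooling with configurable (possibly overlapping) stride."""

    def __init__(self, name, pool=2, stride=1):
        super().__init__(name)
        self.pool = pool
        self.stride = stride

    def out_hw(self, h, w):
        s, p = self.stride, self.pool
        return (h - p) // s + 1, (w - p) // s + 1

    def forward(self, x, train=False):
        p, s = self.pool, self.stride
        win = sliding_window_view(x, (p, p), axis=(1, 2))[:, ::s, ::s]
        out = win.max(axis=(-2, -1))
        self._cache = (x, out)
        return self._maybe_capture_out(np.ascontiguousarray(out))

    def backward(self, gout):
        self._maybe_capture_grad(gout)
        x, out = self._cache
        p, s = self.pool, self.stride
        ho, wo = out.shape[1], out.shape[2]
        dx = np.zeros_like(x)
        taken = np.zeros(out.shape, dtype=bool)
        for di in range(p):
            for dj in range(p):
                sub = x[:, di : di + s * (ho - 1) + 1 : s, dj : dj + s * (wo - 1) + 1 : s, :]
                hit = (~taken) & (sub == out)
                dx[:, di : di + s * (ho - 1) + 1 : s, dj : dj + s * (wo - 1) + 1 : s, :] += np.where(
                    hit, gout, 0.0
                )
                taken |= hit
        return dx


class Flatten(Layer):
    def __init__(self, name):
        super().__init__(name)

    def forward(self, x, train=False):
        self._shape = x.shape
        return self._maybe_capture_out(x.reshape(x.shape[0], -1))

    def backward(self, gout):
        self._maybe_capture_grad(gout)
        return gout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, name, d_in, d_out, rng, activation=None):
        super().__init__(name)
        self.activation = activation
        self.params["W"] = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x, train=False):
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._relu_mask = z > 0
            z = np.where(self._relu_mask, z, 0.0).astype(np.float32)
        self._x = x
        return self._maybe_capture_out(z)

    def backward(self, gout):
        self._maybe_capture_grad(gout)
        if self.activation == "relu":
            gout = np.where(self._relu_mask, gout, 0.0)
        self.grads["W"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        return (gout @ self.params["W"].T).astype(np.float32)


def _sigmoid(z):
    # clip keeps exp() finite in float32 without changing saturated values
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class LSTM(Layer):
    """Single LSTM layer returning the last hidden state.

    Gate order i, f, g, o.  ``dropout`` masks the inputs and
    ``recurrent_dropout`` masks the recurrent state, each with one mask per
    sequence (shared across timesteps), active only in training.  The L2
    penalty on the input kernel is applied by the model's regularization
    step, not here.
    """

    def __init__(
        self,
        name,
        d_in,
        units,
        rng,
        dropout=0.0,
        recurrent_dropout=0.0,
        l2=0.0,
    ):
        super().__init__(name)
        self.d_in = d_in
        self.units = units
        self.dropout = dropout
        self.recurrent_dropout = recurrent_dropout
        self.l2 = l2
        self.rng = np.random.default_rng(0)  # trainer replaces this
        u = units
        self.params["W"] = _glorot(rng, d_in, 4 * u, (d_in, 4 * u))
        self.params["U"] = _glorot(rng, u, 4 * u, (u, 4 * u))
        b = np.zeros(4 * u, dtype=np.float32)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.params["b"] = b

    def forward(self, x, train=False):
        b, t, d = x.shape
        u = self.units
        if train and self.dropout > 0:
            self._in_mask = (
                self.rng.random((b, d)) >= self.dropout
            ).astype(np.float32) / (1.0 - self.dropout)
        else:
            self._in_mask = None
        if train and self.recurrent_dropout > 0:
            self._rec_mask = (
                self.rng.random((b, u)) >= self.recurrent_dropout
            ).astype(np.float32) / (1.0 - self.recurrent_dropout)
        else:
            self._rec_mask = None

        h = np.zeros((b, u), dtype=np.float32)
        c = np.zeros((b, u), dtype=np.float32)
        W, U, bb = self.params["W"], self.params["U"], self.params["b"]
        self._steps = []
        for ti in range(t):
            xt = x[:, ti].astype(np.float32)
            if self._in_mask is not None:
                xt = xt * self._in_mask
            hd = h * self._rec_mask if self._rec_mask is not None else h
            z = xt @ W + hd @ U + bb
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            self._steps.append((xt, hd, i, f, g, o, c_prev, tc))
        self._bt = (b, t)
        return self._maybe_capture_out(h)

    def backward(self, gout):
        self._maybe_capture_grad(gout)
        b, t = self._bt
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros((b, t, self.d_in), dtype=np.float32)
        dh = gout.astype(np.float32)
        dc = np.zeros((b, u), dtype=np.float32)
        for ti in range(t - 1, -1, -1):
            xt, hd, i, f, g, o, c_prev, tc = self._steps[ti]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            ).astype(np.float32)
            dW += xt.T @ dz
            dU += hd.T @ dz
            db += dz.sum(axis=0)
            dxt = dz @ W.T
            if self._in_mask is not None:
                dxt = dxt * self._in_mask
            dx[:, ti] = dxt
            dh = dz @ U.T
            if self._rec_mask is not None:
                dh = dh * self._rec_mask
            dc = dc * f
        self.grads["W"] = dW
        self.grads["U"] = dU
        self.grads["b"] = db
        return dx
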