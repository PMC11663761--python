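"""Minimal NumPy neural-network layers for the slice-bag MIL classifier.

Implements exactly what the model needs — stride-2 3x3 convolutions via
im2col, ReLU, spatial global average pooling, a fully connected layer, a
single-layer LSTM with backprop through time, a numerically stable
sigmoid binary cross-entropy, the AdamW optimiser and a cosine-annealing
learning-rate schedule. Everything runs single-threaded on CPU in
float32 and is deterministic under a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Float dtype for parameters and activations. float32 is the training
#: default; tests switch to float64 for numerical gradient checks.
DTYPE = np.float32

__all__ = [
    "Conv2d",
    "ReLU",
    "GlobalAvgPool2d",
    "BatchNorm2d",
    "GlobalMaxPool2d",
    "Linear",
    "LSTM",
    "AdamW",
    "bce_with_logits",
    "sigmoid",
    "cosine_lr",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean per-category binary cross-entropy on sigmoid probabilities.

    Returns ``(loss, dlogits)``; the stable form
    ``max(z,0) - z*y + log(1+exp(-|z|))`` avoids overflow for large |z|.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("targets must be binary 0/1")
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz


class Layer:
    """Base: parameters and accumulated gradients keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = cin * k * k
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)
        ).astype(DTYPE)
        self.params["b"] = np.zeros(cout, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._cols, self._xshape = cols, x.shape
        out = np.einsum(
            "nchwij,ocij->nohw", cols, self.params["W"], optimize=True
        )
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = self._xshape
        ho, wo = dout.shape[2], dout.shape[3]
        self.grads["W"] += np.einsum(
            "nohw,nchwij->ocij", dout, self._cols, optimize=True
        )
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        dcols = np.einsum(
            "nohw,ocij->nchwij", dout, self.params["W"], optimize=True
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ]
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm2d(Layer):
    """Per-channel normalisation over the bag batch and spatial axes.

    Statistics are computed from the current forward pass — the bag
    sequence of one exam — in training and inference alike, so each exam
    is normalised against its own anatomy and the result is deterministic
    without running averages. With near-constant anatomy across exams this
    is what lets focal deviations (lesions) dominate the feature scale.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        m = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - m) * self._ivar
        self._M = x.shape[0] * x.shape[2] * x.shape[3]
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return (g * self._xhat + b).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        xhat, ivar, M = self._xhat, self._ivar, self._M
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"][None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * ivar
        return dx.astype(dout.dtype)


class GlobalAvgPool2d(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._shape
        ).astype(dout.dtype).copy()


class GlobalMaxPool2d(Layer):
    """Spatial max pool to one value per channel; keeps focal activations
    that average pooling would dilute."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._argmax = flat.argmax(axis=2)
        return flat.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h * w), dtype=dout.dtype)
        ni, ci = np.indices((n, c))
        dflat[ni, ci, self._argmax] = dout
        return dflat.reshape(self._shape)


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(1.0 / din), size=(dout, din)
        ).astype(DTYPE)
        self.params["b"] = np.zeros(dout, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]


class LSTM(Layer):
    """Single-layer unidirectional LSTM over one sequence (T, D) -> (T, H)."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        scale = np.sqrt(1.0 / hidden)
        self.params["Wx"] = rng.normal(0, scale, size=(4 * hidden, din)).astype(DTYPE)
        self.params["Wh"] = rng.normal(0, scale, size=(4 * hidden, hidden)).astype(DTYPE)
        self.params["b"] = np.zeros(4 * hidden, dtype=DTYPE)
        # forget-gate bias 1: standard initialisation for gradient flow
        self.params["b"][hidden : 2 * hidden] = 1.0
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        hdim = self.hidden
        T = x.shape[0]
        h = np.zeros(hdim, dtype=np.float64)
        c = np.zeros(hdim, dtype=np.float64)
        self._x = x
        self._cache = []
        hs = np.empty((T, hdim), dtype=np.float64)
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        for t in range(T):
            z = Wx @ x[t] + Wh @ h + b
            i = sigmoid(z[:hdim])
            f = sigmoid(z[hdim : 2 * hdim])
            g = np.tanh(z[2 * hdim : 3 * hdim])
            o = sigmoid(z[3 * hdim :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            self._cache.append((h.copy(), c_prev, i, f, g, o, tc))
            h = o * tc
            hs[t] = h
        return hs.astype(self.params['Wx'].dtype)

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        hdim = self.hidden
        x = self._x
        T = x.shape[0]
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx, dtype=np.float64)
        dWh = np.zeros_like(Wh, dtype=np.float64)
        db = np.zeros(4 * hdim, dtype=np.float64)
        dx = np.zeros_like(x, dtype=np.float64)
        dh_next = np.zeros(hdim)
        dc_next = np.zeros(hdim)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dhs[t].astype(np.float64) + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ]
            )
            dWx += np.outer(dz, x[t])
            dWh += np.outer(dz, h_prev)
            db += dz
            dx[t] = Wx.T @ dz
            dh_next = Wh.T @ dz
            dc_next = dc * f
        dt = self.params["Wx"].dtype
        self.grads["Wx"] += dWx.astype(dt)
        self.grads["Wh"] += dWh.astype(dt)
        self.grads["b"] += db.astype(dt)
        return dx.astype(dt)


class AdamW:
    """Decoupled weight-decay Adam over a list of layers."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 2.3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ):
        self.layers = [l for l in layers if l.params]
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = b1 * self.m[li][k] + (1 - b1) * g
                self.v[li][k] = b2 * self.v[li][k] + (1 - b2) * g * g
                mhat = self.m[li][k] / bc1
                vhat = self.v[li][k] / bc2
                p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``base_lr`` toward 0 over the training run."""
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))
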