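"""Minimal numpy neural-network layers with explicit backpropagation.

Data layout is ``(N, C, H, W)`` float64 throughout.  Each layer owns its
parameters and gradients in dicts keyed by name; ``forward`` caches what
``backward`` needs.  Only what the compact U-Net requires is implemented:
3x3 and 1x1 convolutions, ReLU, 2x2 max pooling, nearest-neighbour
upsampling, channel concatenation, sigmoid, and a single-head self-attention
block for the optional transformer bottleneck.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: parameterless layers inherit as-is."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """Same-padded 3x3 convolution, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * 9
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        W = self.params["W"]
        y = np.zeros((n, W.shape[0], h, w))
        for di in range(3):
            for dj in range(3):
                # (N,C,H,W) x (C,F) -> (N,H,W,F)
                y += np.tensordot(
                    xp[:, :, di : di + h, dj : dj + w], W[:, :, di, dj], axes=([1], [1])
                ).transpose(0, 3, 1, 2)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        W = self.params["W"]
        dxp = np.zeros_like(xp)
        dW = np.zeros_like(W)
        for di in range(3):
            for dj in range(3):
                xs = xp[:, :, di : di + h, dj : dj + w]
                # dW[f,c] = sum_{n,h,w} dy[n,f,h,w] * xs[n,c,h,w]
                dW[:, :, di, dj] = np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, di : di + h, dj : dj + w] += np.tensordot(
                    dy, W[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.grads["W"][...] = dW
        self.grads["b"][...] = dy.sum(axis=(0, 2, 3))
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.tensordot(x, self.params["W"], axes=([1], [1])).transpose(0, 3, 1, 2)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads["W"][...] = np.tensordot(dy, x, axes=([0, 2, 3], [0, 2, 3]))
        self.grads["b"][...] = dy.sum(axis=(0, 2, 3))
        return np.tensordot(dy, self.params["W"], axes=([1], [0])).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial dims required)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2)
        windows = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = windows.argmax(axis=-1)
        self._in_shape = x.shape
        return windows.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dwin = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dwin, self._argmax[..., None], dy[..., None], axis=-1)
        return (
            dwin.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class SelfAttention(Layer):
    """Single-head self-attention over the flattened spatial grid, with a
    residual connection: ``y = x + softmax(QK'/sqrt(C)) V Wo``."""

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        s = 1.0 / np.sqrt(channels)
        self.params = {
            name: rng.normal(0.0, s, size=(channels, channels))
            for name in ("Wq", "Wk", "Wv", "Wo")
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.channels = channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        X = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, T, C)
        P = self.params
        Q, K, V = X @ P["Wq"], X @ P["Wk"], X @ P["Wv"]
        S = Q @ K.transpose(0, 2, 1) / np.sqrt(c)
        S -= S.max(axis=-1, keepdims=True)
        E = np.exp(S)
        A = E / E.sum(axis=-1, keepdims=True)
        Z = A @ V
        Y = X + Z @ P["Wo"]
        self._cache = (X, Q, K, V, A, Z)
        return Y.transpose(0, 2, 1).reshape(n, c, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        X, Q, K, V, A, Z = self._cache
        P = self.params
        dY = dy.reshape(n, c, h * w).transpose(0, 2, 1)
        dZ = dY @ P["Wo"].T
        self.grads["Wo"][...] = np.einsum("ntc,ntd->cd", Z, dY)
        dA = dZ @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dZ
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = dS @ K / np.sqrt(c)
        dK = dS.transpose(0, 2, 1) @ Q / np.sqrt(c)
        self.grads["Wq"][...] = np.einsum("ntc,ntd->cd", X, dQ)
        self.grads["Wk"][...] = np.einsum("ntc,ntd->cd", X, dK)
        self.grads["Wv"][...] = np.einsum("ntc,ntd->cd", X, dV)
        dX = dY + dQ @ P["Wq"].T + dK @ P["Wk"].T + dV @ P["Wv"].T
        return dX.transpose(0, 2, 1).reshape(n, c, h, w)


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g**2
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
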