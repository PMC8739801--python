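"""Compact NumPy CNN: 3x3 convolutions, ReLU, 2x2 max pooling, global
average pooling and a dense softmax head, trained with Adam.

Everything is deterministic: parameters are initialized from a seeded
generator and the forward/backward passes are pure NumPy, so identical
(architecture, seed, data, epochs) produce bit-identical parameters and
losses on a given platform.

Layout is NHWC.  Convolutions are stride-1 with "same" zero padding and are
evaluated as nine shifted (N, H, W, C) @ (C, F) matmuls, which is fast
enough for the small inputs this package trains on.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Forward/backward interface; params and grads are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 same-padding convolution with He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (9 * c_in))
        self.w = rng.normal(0.0, std, size=(3, 3, c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        self._xpad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        y = np.broadcast_to(self.b, (n, h, w, self.b.shape[0])).copy()
        for di in range(3):
            for dj in range(3):
                y += self._xpad[:, di : di + h, dj : dj + w, :] @ self.w[di, dj]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        dxpad = np.zeros_like(self._xpad)
        dw = self.grads[0]
        dw[...] = 0.0
        for di in range(3):
            for dj in range(3):
                xs = self._xpad[:, di : di + h, dj : dj + w, :]
                dw[di, dj] = np.einsum("nijc,nijf->cf", xs, dy)
                dxpad[:, di : di + h, dj : dj + w, :] += dy @ self.w[di, dj].T
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        return dxpad[:, 1:-1, 1:-1, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties share the gradient equally."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        self._x_shape = x.shape
        mask = xr == y[:, :, None, :, None, :]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        d = self._mask * dy[:, :, None, :, None, :]
        return d.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    """Spatial mean: (n, h, w, c) -> (n, c)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        return np.broadcast_to(dy[:, None, None, :], (n, h, w, c)) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / d_in)
        self.w = rng.normal(0.0, std, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


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
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
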