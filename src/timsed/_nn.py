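"""Minimal CPU neural-network engine for the convolutional encoder.

Implements exactly the layers the backbone needs — 3x3 same-padding
convolution, batch normalization, ReLU, 2x2 max pooling, global average
pooling and a linear head — with explicit forward/backward passes and an
Adam optimizer. Activations are channels-last [N, H, W, C] in float32: the
convolution is computed as nine shifted [*, C_in] @ [C_in, C_out] matrix
products, which keeps every BLAS call contiguous and is markedly faster on
one CPU core than an im2col layout.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape-preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialization
        self.W = Param(rng.normal(0.0, scale, size=(3, 3, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.broadcast_to(self.b.value, (n, h, w, self.W.value.shape[3])).copy()
        for di in range(3):
            for dj in range(3):
                xs = np.ascontiguousarray(xp[:, di:di + h, dj:dj + w, :])
                out += (xs.reshape(-1, c) @ self.W.value[di, dj]).reshape(n, h, w, -1)
        self._xp = xp
        return out

    def backward(self, grad):
        xp = self._xp
        n, h, w, c_out = grad.shape
        c_in = self.W.value.shape[2]
        g2 = np.ascontiguousarray(grad).reshape(-1, c_out)
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xs = np.ascontiguousarray(xp[:, di:di + h, dj:dj + w, :])
                self.W.grad[di, dj][...] = xs.reshape(-1, c_in).T @ g2
                dxp[:, di:di + h, dj:dj + w, :] += \
                    (g2 @ self.W.value[di, dj].T).reshape(n, h, w, c_in)
        self.b.grad[...] = g2.sum(axis=0)
        return np.ascontiguousarray(dxp[:, 1:-1, 1:-1, :])


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[1] * shape[2]
        self.gamma.grad[...] = (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad[...] = grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.value
        gsum = g.sum(axis=(0, 1, 2), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 1, 2), keepdims=True)
        dx = inv * (g - gsum / n_eff - xhat * gx / n_eff)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        xt = xt.transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
        self._argmax = xt.argmax(axis=3)
        self._shape = (n, h, w, c)
        return xt.max(axis=3)

    def backward(self, grad):
        n, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        onehot = (self._argmax[:, :, :, None, :] ==
                  np.arange(4)[None, None, None, :, None])
        g = grad[:, :, :, None, :] * onehot
        g = g.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, :h2 * 2, :w2 * 2, :] = g.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class GlobalAvgPool(Layer):
    """[N, H, W, C] -> [N, C]."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w),
                               (n, h, w, c)).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_out, d_in)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad[...] = grad.T @ self._x
        self.b.grad[...] = grad.sum(axis=0)
        return grad @ self.W.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)
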