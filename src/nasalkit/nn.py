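"""A small, deterministic CNN stack implemented on numpy.

This provides exactly the layers the window classifier needs — 2-D
convolution with "same" padding and stride 1, batch normalization, leaky
ReLU, 2x2 stride-1 max pooling, dense layers, softmax cross-entropy — with
Glorot-uniform initialization and an Adam optimizer, all driven by an
explicit :class:`numpy.random.Generator` so that a given seed yields
bit-identical weights and training trajectories.

Tensors are ``(batch, channels, height, width)`` in float32.  "Same"
padding follows the usual convention for even extents: of the ``k - 1``
padded positions, ``floor((k - 1)/2)`` go before and the rest after.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "LeakyReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_with_softmax",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _same_pad(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k - 1 - (k - 1) // 2


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 "same" 2-D convolution (cross-correlation), linear activation.

    Implemented as a sum of shifted per-offset channel mixes (one small
    matrix product per kernel cell), which avoids materializing im2col
    patch matrices.
    """

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.kh, self.kw = in_ch, out_ch, kh, kw
        fan_in = in_ch * kh * kw
        fan_out = out_ch * kh * kw
        self.w = glorot_uniform(rng, (out_ch, in_ch, kh, kw), fan_in, fan_out)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        self._shape = x.shape
        (pt, pb), (pl, pr) = _same_pad(self.kh), _same_pad(self.kw)
        xp = np.zeros((b, c, h + pt + pb, w + pl + pr), dtype=np.float32)
        xp[:, :, pt : pt + h, pl : pl + w] = x
        self._xp = xp
        out = np.empty((b, self.out_ch, h, w), dtype=np.float32)
        out[:] = self.b[None, :, None, None]
        for i in range(self.kh):
            for j in range(self.kw):
                out += np.einsum(
                    "fc,bchw->bfhw", self.w[:, :, i, j],
                    xp[:, :, i : i + h, j : j + w], optimize=True,
                )
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        (pt, pb), (pl, pr) = _same_pad(self.kh), _same_pad(self.kw)
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        dxp = np.zeros_like(self._xp)
        for i in range(self.kh):
            for j in range(self.kw):
                self.grads[0][:, :, i, j] = np.einsum(
                    "bfhw,bchw->fc", grad, self._xp[:, :, i : i + h, j : j + w],
                    optimize=True,
                )
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "fc,bfhw->bchw", self.w[:, :, i, j], grad, optimize=True,
                )
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        return dxp[:, :, pt : pt + h, pl : pl + w]


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grads[0][...] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        gm = g.mean(axis=(0, 2, 3), keepdims=True)
        gxm = (g * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (g - gm - self._xhat * gxm) * self._istd[None, :, None, None]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class MaxPool2D(Layer):
    """2x2 max pooling with stride 1 and "same" padding (no downsampling)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        self._shape = x.shape
        xp = np.full((b, c, h + 1, w + 1), -np.inf, dtype=np.float32)
        xp[:, :, :h, :w] = x
        self._xp = xp
        out = np.maximum(
            np.maximum(xp[:, :, :h, :w], xp[:, :, :h, 1 : w + 1]),
            np.maximum(xp[:, :, 1 : h + 1, :w], xp[:, :, 1 : h + 1, 1 : w + 1]),
        )
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dxp = np.zeros((b, c, h + 1, w + 1), dtype=np.float32)
        claimed = np.zeros(grad.shape, dtype=bool)
        for i, j in ((0, 0), (0, 1), (1, 0), (1, 1)):
            cand = self._xp[:, :, i : i + h, j : j + w]
            mask = (cand == self._out) & ~claimed  # first-match tie break
            claimed |= mask
            dxp[:, :, i : i + h, j : j + w] += grad * mask
        return dxp[:, :, :h, :w]


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with linear activation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i}.param{j}"] = p.copy()
            if isinstance(layer, BatchNorm2D):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = state[f"layer{i}.param{j}"]
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_softmax(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits.

    ``y`` holds integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
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
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
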