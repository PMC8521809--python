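"""Compact fully connected networks with hand-written backprop and Adam.

The dosing models only need small multilayer perceptrons (tens of units,
two or three layers), so the forward/backward passes are implemented
directly on numpy arrays. Layers cache their inputs during ``forward`` and
release gradients during ``backward``; parameters live in flat per-layer
lists so target networks can be soft-updated elementwise.
"""

from __future__ import annotations

import copy

import numpy as np


class Linear:
    """Affine layer y = xW + b with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, training):
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Sigmoid:
    params: list = []
    grads: list = []

    def forward(self, x, training):
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._y = y
        return y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class BatchNorm:
    """1-D batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._xhat = (x - mu) / np.sqrt(var + self.eps)
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        if training:  # single-sample batch: use running stats, still cache
            self._xhat = xhat
            self._inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        self.g_gamma = (grad * self._xhat).sum(axis=0)
        self.g_beta = grad.sum(axis=0)
        gx_hat = grad * self.gamma
        if n > 1:
            return (
                self._inv_std
                / n
                * (n * gx_hat - gx_hat.sum(axis=0) - self._xhat * (gx_hat * self._xhat).sum(axis=0))
            )
        return gx_hat * self._inv_std

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.g_gamma, self.g_beta]


class MLP:
    """Sequential stack of layers with explicit forward/backward.

    ``hidden_activation`` applies after every hidden linear layer; the
    output layer is linear unless ``output_activation`` is given.
    """

    def __init__(
        self,
        sizes,
        rng: np.random.Generator,
        output_activation: str | None = None,
        batch_norm: bool = False,
    ):
        self.sizes = tuple(sizes)
        self.layers = []
        for i in range(len(sizes) - 1):
            self.layers.append(Linear(sizes[i], sizes[i + 1], rng))
            last = i == len(sizes) - 2
            if not last:
                if batch_norm:
                    self.layers.append(BatchNorm(sizes[i + 1]))
                self.layers.append(ReLU())
            elif output_activation == "sigmoid":
                self.layers.append(Sigmoid())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Backpropagate ``grad`` (dLoss/dOutput); returns dLoss/dInput."""
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def copy(self) -> "MLP":
        return copy.deepcopy(self)

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.params])

    def set_from(self, other: "MLP") -> None:
        for p, q in zip(self.params, other.params):
            p[...] = q


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def soft_update(target: MLP, online: MLP, coeff: float) -> None:
    """Polyak update: target <- coeff * online + (1 - coeff) * target."""
    tp, op = target.params, online.params
    if len(tp) != len(op) or any(a.shape != b.shape for a, b in zip(tp, op)):
        raise ValueError("target/online parameter shapes do not match")
    for a, b in zip(tp, op):
        a *= 1.0 - coeff
        a += coeff * b
    if isinstance(target.layers, list):  # carry running stats for batch norm
        for lt, lo in zip(target.layers, online.layers):
            if isinstance(lt, BatchNorm):
                lt.running_mean = (1 - coeff) * lt.running_mean + coeff * lo.running_mean
                lt.running_var = (1 - coeff) * lt.running_var + coeff * lo.running_var
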