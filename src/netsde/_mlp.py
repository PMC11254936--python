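"""Compact fully-connected networks with analytic backprop and Adam.

Small tanh MLPs (default two hidden layers) sized for node dimensions d <= 3
and networks of tens of nodes.  Forward passes cache activations; backward
returns parameter gradients and, when needed, the gradient with respect to the
inputs.  Everything is plain NumPy and deterministic under a seeded Generator.
"""

from __future__ import annotations

import numpy as np


class MLP:
    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.dims = list(dims)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-scale, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """Return (output, cache); hidden activations are tanh, output linear."""
        h = np.asarray(X, dtype=float)
        cache = [h]
        n_layers = len(self.W)
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = z if k == n_layers - 1 else np.tanh(z)
            cache.append(h)
        return h, cache

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, cache: list, grad_out: np.ndarray,
                 need_input_grad: bool = False) -> tuple[list[np.ndarray], np.ndarray | None]:
        """Backprop grad_out (same shape as the output) through the cached pass."""
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        g = np.asarray(grad_out, dtype=float)
        for k in range(len(self.W) - 1, -1, -1):
            h_in = cache[k]
            if k != len(self.W) - 1:
                g = g * (1.0 - cache[k + 1] ** 2)  # tanh'
            gW[k] = h_in.T @ g
            gb[k] = g.sum(axis=0)
            if k > 0 or need_input_grad:
                g = g @ self.W[k].T
        return gW + gb, (g if need_input_grad else None)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
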