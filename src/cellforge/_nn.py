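"""Minimal feed-forward network toolkit: linear layers, 2-layer MLP blocks,
reverse-mode gradients by hand, and an Adam optimizer.

Layers cache their last forward inputs, so the usage contract is strictly
forward -> backward -> update within a single thread.  Everything is plain
float64 numpy, which keeps training bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Linear:
    """Affine layer y = x W + b with cached-input backprop."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_scale: float | None = None, b_init: float = 0.0):
        scale = w_scale if w_scale is not None else np.sqrt(2.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.full(n_out, float(b_init))
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    def params_and_grads(self):
        yield self.W, self.gW
        yield self.b, self.gb


class MLP2:
    """Two-layer perceptron block: Linear -> ReLU -> Linear."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 rng: np.random.Generator):
        self.l1 = Linear(n_in, n_hidden, rng)
        self.l2 = Linear(n_hidden, n_out, rng)
        self._h: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._h = self.l1.forward(x)
        return self.l2.forward(relu(self._h))

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.l2.backward(g)
        g = g * (self._h > 0)
        return self.l1.backward(g)

    def params_and_grads(self):
        yield from self.l1.params_and_grads()
        yield from self.l2.params_and_grads()


class Embedding:
    """Lookup table with scatter-add gradients (used for label embeddings)."""

    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.1):
        self.E = rng.standard_normal((n_rows, dim)) * scale
        self.gE = np.zeros_like(self.E)
        self._idx: np.ndarray | None = None

    def forward(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.E.shape[0]):
            raise IndexError(
                f"label index out of vocabulary [0, {self.E.shape[0]})"
            )
        self._idx = idx
        return self.E[idx]

    def backward(self, g: np.ndarray) -> None:
        np.add.at(self.gE, self._idx, g)

    def params_and_grads(self):
        yield self.E, self.gE


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0
                         ) -> np.ndarray:
    """Transformer-style sinusoidal position features for time steps."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(args), np.sin(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb


class Adam:
    """Adam over a list of (param, grad) array pairs held by modules."""

    def __init__(self, modules, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = [pg for m in modules for pg in m.params_and_grads()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0.0
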