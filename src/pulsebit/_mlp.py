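"""Small numpy multilayer perceptron trained with a per-sample logit offset.

The decoder predicts a logit *update* u to a prior pulse logit; the
binary cross-entropy is evaluated at u + prior, so the gradient at the
output is sigmoid(u + prior) - x.  Two leaky-ReLU hidden layers, Adam
updates.  Kept dependency-free so the training loop stays transparent
and deterministic under a seed.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Elementwise -log p(x) for p = sigmoid(z), numerically stable (nats)."""
    return np.maximum(z, 0.0) - z * x + np.log1p(np.exp(-np.abs(z)))


class OffsetMLP:
    """MLP computing a scalar logit update; hidden sizes default (40, 20)."""

    def __init__(self, n_in: int, hidden: tuple[int, ...] = (40, 20),
                 leak: float = 0.01, seed: int = 0):
        rng = np.random.default_rng(seed)
        sizes = [n_in, *hidden, 1]
        self.leak = leak
        self.W = []
        self.b = []
        for i, (a, c) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = np.sqrt(2.0 / a)
            if i == len(sizes) - 2:
                scale *= 0.01  # near-zero initial update: start at the prior
            self.W.append(rng.normal(0.0, scale, size=(a, c)))
            self.b.append(np.zeros(c))
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        a = X
        acts = [X]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < len(self.W) - 1:
                a = np.where(z > 0, z, self.leak * z)
                acts.append(a)
            else:
                a = z
        u = a[:, 0]
        return (u, acts) if cache else u

    def backward(self, acts, d_u: np.ndarray):
        """Gradients of mean loss given dL/du per sample (already /n)."""
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        delta = d_u[:, None]
        for i in range(len(self.W) - 1, -1, -1):
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                delta = np.where(acts[i] > 0, delta, self.leak * delta)
        return grads_W, grads_b

    def adam_step(self, grads_W, grads_b, lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        grads = grads_W + grads_b
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- (de)serialization --------------------------------------------------
    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, W, b):
        self.W = [np.asarray(w, dtype=np.float64).copy() for w in W]
        self.b = [np.asarray(x, dtype=np.float64).copy() for x in b]
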