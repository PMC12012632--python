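"""Minimal neural-network primitives on numpy.

All models in this package (autoencoder, decoder-only transformer, LSTM)
are small enough that hand-written forward/backward passes on numpy are
fast on one CPU; this module holds the pieces they share: parameter
initialization, the Adam optimizer, softmax/cross-entropy, and layer norm.
Parameters live in plain ``dict[str, np.ndarray]`` pytrees.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "softmax", "cross_entropy", "layer_norm", "layer_norm_backward",
           "glorot", "clip_gradients"]


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood of integer targets under `probs[..., v]`."""
    p = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


def layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5):
    """Normalize the last axis; returns (out, cache for backward)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def layer_norm_backward(dout: np.ndarray, cache):
    xhat, inv, g = cache
    n = xhat.shape[-1]
    dg = (dout * xhat).reshape(-1, n).sum(axis=0)
    db = dout.reshape(-1, n).sum(axis=0)
    dxhat = dout * g
    dx = inv / n * (
        n * dxhat
        - dxhat.sum(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
    )
    return dx, dg, db


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Global-norm gradient clipping in place; returns the pre-clip norm."""
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            self.params[k] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
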