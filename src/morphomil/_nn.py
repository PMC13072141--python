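"""Minimal neural-network primitives shared by the model modules.

Plain-numpy parameter containers, Xavier-uniform initialization, numerically
stable activations, an Adam optimizer and global-norm gradient clipping.
Gradients are derived by hand in the modules that own each architecture.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np
from scipy.special import expit as sigmoid  # noqa: F401  (re-exported)

Params = Dict[str, np.ndarray]


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape=None) -> np.ndarray:
    """Xavier/Glorot uniform sample U(-a, a), a = sqrt(6 / (fan_in+fan_out))."""
    if shape is None:
        shape = (fan_in, fan_out)
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax with max-subtraction for numerical stability."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def clip_global_norm(grads: Params, max_norm: float) -> Params:
    """Scale all gradients jointly so their global L2 norm is <= max_norm."""
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total <= max_norm or total == 0.0:
        return grads
    scale = max_norm / total
    return {k: g * scale for k, g in grads.items()}


class Adam:
    """Adaptive-moment optimizer over a named parameter dictionary."""

    def __init__(self, params: Params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
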