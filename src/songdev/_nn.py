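"""Minimal feedforward-network machinery (dense layers, backprop, Adam).

Both learned models in this package are small multilayer perceptrons: the
predicted-age regressor (tanh hidden units, trained full-batch) and the
time-varying Gaussian density network (ReLU hidden units, trained with
mini-batch Adam).  The networks are small enough (<150k parameters) that a
plain numpy implementation with hand-written gradients is fast, dependency
free, and bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "Adam"]

_ACTS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),  # derivative in terms of activation
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(a.dtype)),
}


@dataclass
class MLP:
    """Fully connected network with identical hidden activations, linear output.

    Parameters are stored as lists of (weight, bias) arrays; ``weights[i]`` has
    shape (fan_in, fan_out).  ``hidden`` lists hidden-layer widths; an empty
    list gives a purely linear map.
    """

    n_in: int
    hidden: list[int]
    n_out: int
    activation: str = "tanh"
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def init(self, rng: np.random.Generator) -> "MLP":
        sizes = [self.n_in, *self.hidden, self.n_out]
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in) if self.activation == "relu" else np.sqrt(1.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        return self

    # -- parameter vector interface (used by the L-BFGS training path) -------
    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def get_flat(self) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)])

    def set_flat(self, theta: np.ndarray) -> None:
        i = 0
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[li] = theta[i : i + w.size].reshape(w.shape)
            i += w.size
            self.biases[li] = theta[i : i + b.size].copy()
            i += b.size
        if i != theta.size:
            raise ValueError(f"parameter vector length {theta.size} != {self.n_params}")

    # -- forward / backward ---------------------------------------------------
    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Map (n, n_in) -> (n, n_out). If ``cache`` is a list, activations are
        appended to it for a subsequent :meth:`backward` call."""
        act, _ = _ACTS[self.activation]
        a = np.asarray(x, dtype=float)
        if cache is not None:
            cache.append(a)
        n_layers = len(self.weights)
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            a = z if li == n_layers - 1 else act(z)
            if cache is not None:
                cache.append(a)
        return a

    def backward(self, cache: list, d_out: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of a scalar loss wrt parameters given d(loss)/d(output)."""
        _, dact = _ACTS[self.activation]
        grads_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore[list-item]
        delta = np.asarray(d_out, dtype=float)
        for li in range(len(self.weights) - 1, -1, -1):
            a_prev = cache[li]
            grads_w[li] = a_prev.T @ delta
            grads_b[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.weights[li].T) * dact(cache[li])
        return grads_w, grads_b

    def copy_params(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_params(self, params: tuple[list[np.ndarray], list[np.ndarray]]) -> None:
        self.weights = [w.copy() for w in params[0]]
        self.biases = [b.copy() for b in params[1]]

    def weight_sq_sum(self) -> float:
        """Sum of squared connection weights (biases excluded), the L2 term."""
        return float(sum((w * w).sum() for w in self.weights))


class Adam:
    """Standard Adam optimizer over an MLP's (weights, biases) lists."""

    def __init__(self, mlp: MLP, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.mlp = mlp
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m_w = [np.zeros_like(w) for w in mlp.weights]
        self.v_w = [np.zeros_like(w) for w in mlp.weights]
        self.m_b = [np.zeros_like(b) for b in mlp.biases]
        self.v_b = [np.zeros_like(b) for b in mlp.biases]

    def step(self, grads_w: list[np.ndarray], grads_b: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for i, g in enumerate(grads_w):
            self.m_w[i] = b1 * self.m_w[i] + (1 - b1) * g
            self.v_w[i] = b2 * self.v_w[i] + (1 - b2) * g * g
            self.mlp.weights[i] -= self.lr * (self.m_w[i] / corr1) / (np.sqrt(self.v_w[i] / corr2) + self.eps)
        for i, g in enumerate(grads_b):
            self.m_b[i] = b1 * self.m_b[i] + (1 - b1) * g
            self.v_b[i] = b2 * self.v_b[i] + (1 - b2) * g * g
            self.mlp.biases[i] -= self.lr * (self.m_b[i] / corr1) / (np.sqrt(self.v_b[i] / corr2) + self.eps)
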