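"""Minimal fully-connected network stack used by the hierarchical model.

Rectifier activations, inverted dropout, a linear class head with
normalized-exponential (softmax) output, cross-entropy loss and Adam.
Everything is plain NumPy with explicit backward passes so gradients can
flow end-to-end through the softmax -> mean-aggregation -> concatenation
chain of the hierarchy. All randomness goes through seeded Generators,
so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "softmax", "softmax_backward", "cross_entropy_grad"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient through softmax: dL/dz given p = softmax(z) and dL/dp."""
    return p * (dp - np.sum(dp * p, axis=-1, keepdims=True))


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class MLP:
    """Fully-connected net: hidden ReLU(+dropout) layers and a linear head.

    ``widths`` gives the input and hidden sizes, e.g. ``(12, 256, 64)``;
    the head maps the last hidden layer to ``n_classes`` logits. The last
    hidden activation doubles as the level's embedding.
    """

    def __init__(
        self,
        widths: tuple[int, ...],
        n_classes: int,
        dropout: float = 0.2,
        seed: int = 0,
    ) -> None:
        if len(widths) < 2:
            raise ValueError("need at least an input and one hidden width")
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.n_classes = n_classes
        self.dropout = dropout
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        dims = list(widths) + [n_classes]
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
            self.b.append(np.zeros(d_out))

    @property
    def n_hidden(self) -> int:
        return len(self.widths) - 1

    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(
        self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        """Return logits and a cache for the backward pass."""
        a = np.asarray(X, dtype=float)
        cache = {"inputs": [], "masks": []}
        for l in range(self.n_hidden):
            cache["inputs"].append(a)
            z = a @ self.W[l] + self.b[l]
            a = np.maximum(z, 0.0)
            if train and self.dropout > 0:
                if rng is None:
                    raise ValueError("training forward pass requires an rng")
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
            else:
                mask = None
            cache["masks"].append(mask)
        cache["inputs"].append(a)
        logits = a @ self.W[-1] + self.b[-1]
        return logits, cache

    def backward(
        self, cache: dict, dlogits: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Gradients (dW, db, dX) from the upstream logit gradient."""
        dW = [np.zeros_like(w) for w in self.W]
        db = [np.zeros_like(b) for b in self.b]
        a_last = cache["inputs"][-1]
        dW[-1] = a_last.T @ dlogits
        db[-1] = dlogits.sum(axis=0)
        da = dlogits @ self.W[-1].T
        for l in range(self.n_hidden - 1, -1, -1):
            mask = cache["masks"][l]
            if mask is not None:
                da = da * mask
            a_in = cache["inputs"][l]
            z = a_in @ self.W[l] + self.b[l]
            dz = da * (z > 0)
            dW[l] = a_in.T @ dz
            db[l] = dz.sum(axis=0)
            da = dz @ self.W[l].T
        return dW, db, da

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X, train=False)
        return softmax(logits)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
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
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
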