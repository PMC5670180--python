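"""Minimal feed-forward neural-network core (NumPy).

Dense layers with ReLU/sigmoid activations, inverted dropout, mini-batch
SGD and ADADELTA, and reverse-mode gradients for the two losses used by
the model: mean-squared-error reconstruction (autoencoder pretraining)
and binary cross-entropy (association classification).  Everything is
driven by explicit ``numpy.random.Generator`` instances so that training
is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "relu",
    "sigmoid",
    "Dense",
    "SGD",
    "Adadelta",
    "FeedForward",
    "bce_loss",
    "mse_loss",
]


def relu(x):
    """Rectified linear unit: max(x, 0), elementwise."""
    return np.maximum(x, 0.0)


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)), numerically stable."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACTIVATIONS = {"relu": relu, "sigmoid": sigmoid, "linear": lambda x: x}


def _act_grad(name: str, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (pre > 0).astype(np.float64)
    if name == "sigmoid":
        return post * (1.0 - post)
    return np.ones_like(pre)


class Dense:
    """Fully connected layer ``act(X @ W + b)`` with cached forward state."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str,
        rng: np.random.Generator,
        weight_init_std: float = 0.05,
        bias_init_range: tuple[float, float] = (-1.0, 0.0),
    ) -> None:
        self.W = rng.normal(0.0, weight_init_std, size=(n_in, n_out))
        self.b = rng.uniform(*bias_init_range, size=n_out)
        self.activation = activation
        self._x: np.ndarray | None = None
        self._pre: np.ndarray | None = None
        self._post: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        pre = x @ self.W + self.b
        post = _ACTIVATIONS[self.activation](pre)
        if cache:
            self._x, self._pre, self._post = x, pre, post
        return post

    def backward(self, d_post: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Gradient w.r.t. input and parameters from d(loss)/d(activation)."""
        d_pre = d_post * _act_grad(self.activation, self._pre, self._post)
        gW = self._x.T @ d_pre
        gb = d_pre.sum(axis=0)
        dx = d_pre @ self.W.T
        return dx, gW, gb


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, lr: float = 0.05) -> None:
        self.lr = lr

    def step(self, layer: Dense, gW: np.ndarray, gb: np.ndarray) -> None:
        layer.W -= self.lr * gW
        layer.b -= self.lr * gb


class Adadelta:
    """ADADELTA: per-parameter adaptive steps from running gradient
    and update moments; no hand-set learning rate required (``lr`` is the
    conventional global multiplier, 1.0)."""

    def __init__(self, rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0) -> None:
        self.rho, self.eps, self.lr = rho, eps, lr
        self._state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def _update(self, key: tuple[int, str], param: np.ndarray, grad: np.ndarray) -> None:
        if key not in self._state:
            self._state[key] = (np.zeros_like(param), np.zeros_like(param))
        eg2, edx2 = self._state[key]
        eg2 = self.rho * eg2 + (1.0 - self.rho) * grad**2
        delta = -np.sqrt(edx2 + self.eps) / np.sqrt(eg2 + self.eps) * grad
        edx2 = self.rho * edx2 + (1.0 - self.rho) * delta**2
        param += self.lr * delta
        self._state[key] = (eg2, edx2)

    def step(self, layer: Dense, gW: np.ndarray, gb: np.ndarray) -> None:
        self._update((id(layer), "W"), layer.W, gW)
        self._update((id(layer), "b"), layer.b, gb)


def bce_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Binary cross-entropy  -(1/n) sum [y ln a + (1-y) ln(1-a)]."""
    a = np.clip(scores, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(a) + (1.0 - labels) * np.log(1.0 - a)))


def mse_loss(recon: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((recon - target) ** 2))


class FeedForward:
    """A stack of dense layers with dropout after every hidden layer.

    ``widths`` includes the input width; ``activations`` has one entry per
    weight layer.  Dropout (inverted, so inference needs no rescaling) is
    applied to hidden activations only, and only when a training-time
    ``dropout_rng`` is passed to :meth:`forward`.
    """

    def __init__(
        self,
        widths: list[int],
        activations: list[str],
        rng: np.random.Generator,
        weight_init_std: float = 0.05,
        bias_init_range: tuple[float, float] = (-1.0, 0.0),
        dropout_rate: float = 0.5,
    ) -> None:
        if len(activations) != len(widths) - 1:
            raise ValueError("need one activation per weight layer")
        self.layers = [
            Dense(widths[i], widths[i + 1], activations[i], rng, weight_init_std, bias_init_range)
            for i in range(len(widths) - 1)
        ]
        self.dropout_rate = dropout_rate
        self._masks: list[np.ndarray | None] = []

    def forward(
        self, x: np.ndarray, cache: bool = False, dropout_rng: np.random.Generator | None = None
    ) -> np.ndarray:
        self._masks = []
        h = x
        for k, layer in enumerate(self.layers):
            h = layer.forward(h, cache=cache)
            is_hidden = k < len(self.layers) - 1
            if is_hidden and dropout_rng is not None and self.dropout_rate > 0.0:
                keep = 1.0 - self.dropout_rate
                mask = (dropout_rng.random(h.shape) < keep) / keep
                h = h * mask
                self._masks.append(mask)
            else:
                self._masks.append(None)
        return h

    def backward(self, d_out: np.ndarray) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """Backprop from d(loss)/d(final activation); returns d_input and
        per-layer parameter gradients (input-to-output order)."""
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.layers)
        d = d_out
        for k in range(len(self.layers) - 1, -1, -1):
            if self._masks and self._masks[k] is not None:
                d = d * self._masks[k]
            d, gW, gb = self.layers[k].backward(d)
            grads[k] = (gW, gb)
        return d, grads

    def apply_grads(self, optimizer, grads) -> None:
        for layer, (gW, gb) in zip(self.layers, grads):
            optimizer.step(layer, gW, gb)

    def snapshot(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(l.W.copy(), l.b.copy()) for l in self.layers]

    def restore(self, snap) -> None:
        for layer, (W, b) in zip(self.layers, snap):
            layer.W[...] = W
            layer.b[...] = b


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index batches covering 0..n-1 once."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
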