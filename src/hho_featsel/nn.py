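"""A compact feed-forward binary classifier in pure numpy.

The screening model is a small dense network — by default five hidden
layers with softsign activations and a single sigmoid output trained with
binary cross-entropy under Adam.  Because the surrounding experiment design
sweeps activations (ReLU, ELU, tanh, Softmax, SELU, Softplus, Softsign) and
first-order optimizers (Adam, NAdam, SGD, RMSprop, Adagrad, Adadelta,
Adamax), both families are implemented here explicitly; each is a few lines
of numpy and the whole trainer is single-threaded and exactly reproducible
from a seed.

Inputs are standardized internally (train-set mean/std) before entering the
network; tabular features on wildly different scales (counts vs. normalized
distances) otherwise stall sigmoid-saturating activations.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["ACTIVATIONS", "OPTIMIZERS", "MLPBinaryClassifier"]

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# name -> (forward, backward); backward maps (z, activation, upstream grad)
# to the gradient w.r.t. z.
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a, g: g * (z > 0)),
    "elu": (
        lambda z: np.where(z > 0, z, np.expm1(np.minimum(z, 0.0))),
        lambda z, a, g: g * np.where(z > 0, 1.0, a + 1.0),
    ),
    "selu": (
        lambda z: _SELU_LAMBDA
        * np.where(z > 0, z, _SELU_ALPHA * np.expm1(np.minimum(z, 0.0))),
        lambda z, a, g: g
        * _SELU_LAMBDA
        * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0))),
    ),
    "tanh": (np.tanh, lambda z, a, g: g * (1.0 - a * a)),
    "softplus": (
        lambda z: np.logaddexp(0.0, z),
        lambda z, a, g: g * _sigmoid(z),
    ),
    "softsign": (
        lambda z: z / (1.0 + np.abs(z)),
        lambda z, a, g: g / (1.0 + np.abs(z)) ** 2,
    ),
    "sigmoid": (_sigmoid, lambda z, a, g: g * a * (1.0 - a)),
    "softmax": (
        _softmax,
        lambda z, a, g: (g - (g * a).sum(axis=1, keepdims=True)) * a,
    ),
    "linear": (lambda z: z, lambda z, a, g: g),
}


class _FirstOrderOptimizer:
    """Per-parameter state for a first-order update rule."""

    def __init__(self, name: str, lr: float | None):
        if name not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {name!r}; supported: {sorted(OPTIMIZERS)}"
            )
        self.name = name
        self.lr = OPTIMIZERS[name] if lr is None else lr
        self.t = 0
        self.state: dict[int, dict[str, np.ndarray]] = {}

    def _slot(self, i: int, like: np.ndarray, *keys: str) -> dict[str, np.ndarray]:
        if i not in self.state:
            self.state[i] = {k: np.zeros_like(like) for k in keys}
        return self.state[i]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        eps = 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.name == "sgd":
                p -= self.lr * g
            elif self.name == "adam":
                s = self._slot(i, p, "m", "v")
                s["m"] = 0.9 * s["m"] + 0.1 * g
                s["v"] = 0.999 * s["v"] + 0.001 * g * g
                m_hat = s["m"] / (1.0 - 0.9**self.t)
                v_hat = s["v"] / (1.0 - 0.999**self.t)
                p -= self.lr * m_hat / (np.sqrt(v_hat) + eps)
            elif self.name == "nadam":
                s = self._slot(i, p, "m", "v")
                s["m"] = 0.9 * s["m"] + 0.1 * g
                s["v"] = 0.999 * s["v"] + 0.001 * g * g
                m_hat = s["m"] / (1.0 - 0.9 ** (self.t + 1))
                v_hat = s["v"] / (1.0 - 0.999**self.t)
                nesterov = 0.9 * m_hat + 0.1 * g / (1.0 - 0.9**self.t)
                p -= self.lr * nesterov / (np.sqrt(v_hat) + eps)
            elif self.name == "rmsprop":
                s = self._slot(i, p, "v")
                s["v"] = 0.9 * s["v"] + 0.1 * g * g
                p -= self.lr * g / (np.sqrt(s["v"]) + eps)
            elif self.name == "adagrad":
                s = self._slot(i, p, "v")
                s["v"] += g * g
                p -= self.lr * g / (np.sqrt(s["v"]) + eps)
            elif self.name == "adadelta":
                s = self._slot(i, p, "v", "u")
                rho = 0.95
                s["v"] = rho * s["v"] + (1 - rho) * g * g
                delta = np.sqrt(s["u"] + eps) / np.sqrt(s["v"] + eps) * g
                s["u"] = rho * s["u"] + (1 - rho) * delta * delta
                p -= self.lr * delta
            elif self.name == "adamax":
                s = self._slot(i, p, "m", "v")
                s["m"] = 0.9 * s["m"] + 0.1 * g
                s["v"] = np.maximum(0.999 * s["v"], np.abs(g))
                p -= self.lr / (1.0 - 0.9**self.t) * s["m"] / (s["v"] + eps)


# conventional default learning rates per rule
OPTIMIZERS: dict[str, float] = {
    "sgd": 0.01,
    "adam": 0.001,
    "nadam": 0.001,
    "rmsprop": 0.001,
    "adagrad": 0.01,
    "adadelta": 1.0,
    "adamax": 0.002,
}


class MLPBinaryClassifier:
    """Dense feed-forward network with a single sigmoid output unit.

    Parameters
    ----------
    hidden_layers : widths of the dense hidden layers, input to output.
    activation : hidden activation name (see ``ACTIVATIONS``).
    optimizer : update rule name (see ``OPTIMIZERS``).
    epochs, batch_size : minibatch training schedule.
    learning_rate : override for the optimizer's conventional default.
    seed : controls weight init and minibatch shuffling.
    standardize : z-score inputs with train-set statistics (default on).
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (64, 32, 16, 8, 4),
        activation: str = "softsign",
        optimizer: str = "adam",
        epochs: int = 600,
        batch_size: int = 64,
        learning_rate: float | None = None,
        seed: int = 0,
        standardize: bool = True,
    ):
        if activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {activation!r}; supported: {sorted(ACTIVATIONS)}"
            )
        if optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {optimizer!r}; supported: {sorted(OPTIMIZERS)}"
            )
        if epochs < 1:
            raise ValueError("epochs must be at least 1")
        if batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if not hidden_layers:
            raise ValueError("need at least one hidden layer")
        self.hidden_layers = tuple(int(w) for w in hidden_layers)
        self.activation = activation
        self.optimizer = optimizer
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.standardize = standardize
        self.weights: list[np.ndarray] | None = None
        self.biases: list[np.ndarray] | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    # -- construction -----------------------------------------------------
    def initialize(self, input_dim: int) -> "MLPBinaryClassifier":
        """Glorot-uniform weight init, seeded; safe to call before ``fit``."""
        if input_dim < 1:
            raise ValueError("input_dim must be at least 1")
        rng = np.random.default_rng(self.seed)
        widths = (int(input_dim),) + self.hidden_layers + (1,)
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._input_dim = int(input_dim)
        return self

    @property
    def n_parameters(self) -> int:
        if self.weights is None:
            raise RuntimeError("network not initialized")
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    # -- training ---------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPBinaryClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        if self.weights is None or X.shape[1] != self._input_dim:
            self.initialize(X.shape[1])
        if self.standardize:
            self._mu = X.mean(axis=0)
            self._sd = X.std(axis=0)
            self._sd[self._sd < 1e-12] = 1.0
            X = (X - self._mu) / self._sd
        rng = np.random.default_rng(self.seed + 1)  # separate stream from init
        opt = _FirstOrderOptimizer(self.optimizer, self.learning_rate)
        act_f, act_b = ACTIVATIONS[self.activation]
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                xb, yb = X[batch], y[batch]
                # forward
                zs, acts = [], [xb]
                a = xb
                for w, b in zip(self.weights[:-1], self.biases[:-1]):
                    z = a @ w + b
                    a = act_f(z)
                    zs.append(z)
                    acts.append(a)
                z_out = a @ self.weights[-1] + self.biases[-1]
                p = _sigmoid(z_out).reshape(-1)
                # backward: BCE + sigmoid gives (p - y) at the output pre-act
                delta = ((p - yb) / len(batch)).reshape(-1, 1)
                grads_w = [np.empty(0)] * len(self.weights)
                grads_b = [np.empty(0)] * len(self.biases)
                grads_w[-1] = acts[-1].T @ delta
                grads_b[-1] = delta.sum(axis=0)
                g = delta @ self.weights[-1].T
                for layer in range(len(self.weights) - 2, -1, -1):
                    g = act_b(zs[layer], acts[layer + 1], g)
                    grads_w[layer] = acts[layer].T @ g
                    grads_b[layer] = g.sum(axis=0)
                    if layer > 0:
                        g = g @ self.weights[layer].T
                opt.step(self.weights + self.biases, grads_w + grads_b)
        return self

    # -- inference --------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise RuntimeError("network not fitted")
        X = np.asarray(X, dtype=float)
        if self.standardize and self._mu is not None:
            X = (X - self._mu) / self._sd
        act_f, _ = ACTIVATIONS[self.activation]
        a = X
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = act_f(a @ w + b)
        return _sigmoid(a @ self.weights[-1] + self.biases[-1]).reshape(-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)
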