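"""Fully connected multi-layer perceptron trained from scratch with NumPy.

Architectures are small stacks of fully connected layers (rectifier hidden
units, softmax output) trained by mini-batch stochastic gradient descent
with Nesterov momentum on the categorical cross-entropy.  The module keeps
both the initial and final parameter snapshots so that the connectivity
graph can be compared before and after learning.

Optimizer conventions follow the legacy Keras SGD: the effective learning
rate at update ``t`` (counting from 0) is ``lr / (1 + decay * t)`` and the
Nesterov step is ``v <- mu*v - lr_t*g;  w <- w + mu*v - lr_t*g``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import Dataset
from .errors import DimensionError, DivergenceError, InvalidConfigurationError

__all__ = [
    "ARCHITECTURE_PRESETS",
    "MLPArchitecture",
    "MLPParameters",
    "TrainConfig",
    "TrainResult",
    "init_normal",
    "init_orthogonal",
    "init_glorot",
    "initialize",
    "forward",
    "predict",
    "accuracy",
    "cross_entropy",
    "train",
]

#: Named presets; the name doubles as the default RNG seed.
ARCHITECTURE_PRESETS: dict[str, list[int]] = {
    "240120": [31, 20, 10, 4],
    "250120": [31, 20, 20, 4],
    "180112": [31, 30, 30, 4],
}


@dataclass(frozen=True)
class MLPArchitecture:
    """Layer sizes of a fully connected net: input, hidden..., output."""

    layer_sizes: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise InvalidConfigurationError("need at least input and output layers")
        if any(s < 1 for s in self.layer_sizes):
            raise InvalidConfigurationError("layer sizes must be positive")

    @classmethod
    def from_preset(cls, name: str) -> "MLPArchitecture":
        try:
            sizes = ARCHITECTURE_PRESETS[name]
        except KeyError as err:
            raise InvalidConfigurationError(
                f"unknown architecture preset {name!r}"
            ) from err
        return cls(tuple(sizes), name=name)

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes) - 1

    @property
    def n_weights(self) -> int:
        return sum(a * b for a, b in zip(self.layer_sizes, self.layer_sizes[1:]))


@dataclass
class MLPParameters:
    """Per-layer weight matrices (fan-in x fan-out) and bias vectors."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise DimensionError("weights and biases must pair per layer")
        for w, b in zip(self.weights, self.biases):
            if w.ndim != 2 or b.ndim != 1 or w.shape[1] != b.shape[0]:
                raise DimensionError("bias length must equal layer fan-out")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)

    def copy(self) -> "MLPParameters":
        return MLPParameters([w.copy() for w in self.weights],
                             [b.copy() for b in self.biases])

    def all_weights(self) -> np.ndarray:
        """All connection weights pooled across layers (biases excluded)."""
        return np.concatenate([w.ravel() for w in self.weights])

    def save_json(self, path: str | Path) -> None:
        payload = {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load_json(cls, path: str | Path) -> "MLPParameters":
        payload = json.loads(Path(path).read_text())
        return cls(
            [np.asarray(w, dtype=float) for w in payload["weights"]],
            [np.asarray(b, dtype=float) for b in payload["biases"]],
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings; defaults are the reference configuration
    (lr 0.01, inverse-time decay 1e-6 per update, Nesterov momentum 0.6)."""

    learning_rate: float = 0.01
    decay: float = 1e-6
    momentum: float = 0.6
    batch_size: int = 32
    max_epochs: int = 200
    init_scheme: str = "normal"
    seed: int = 0
    stop_at_perfect: bool = False

    def __post_init__(self) -> None:
        if self.init_scheme not in ("normal", "orthogonal", "glorot"):
            raise InvalidConfigurationError(
                f"unknown init_scheme {self.init_scheme!r}"
            )
        if self.batch_size < 1 or self.max_epochs < 1:
            raise InvalidConfigurationError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainResult:
    initial_params: MLPParameters
    final_params: MLPParameters
    accuracy_trace: list[float] = field(default_factory=list)
    loss_trace: list[float] = field(default_factory=list)
    epochs_to_perfect: int | None = None
    epochs_run: int = 0


# ---------------------------------------------------------------------------
# Initialization schemes
# ---------------------------------------------------------------------------

def init_normal(shape: tuple[int, int], rng: np.random.Generator,
                std: float = 0.1) -> np.ndarray:
    """Gaussian entries, mean 0, standard deviation ``std`` (default 0.1)."""
    return rng.normal(0.0, std, size=shape)


def init_orthogonal(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """(Semi-)orthogonal matrix from QR of a Gaussian draw.

    For an n x m result the shorter axis is orthonormal: W @ W.T = I_n when
    n <= m, W.T @ W = I_m otherwise.
    """
    n, m = shape
    a = rng.normal(0.0, 1.0, size=(max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix the factorization's sign ambiguity
    return q.T if n < m else q


def init_glorot(fan_in: int, fan_out: int, k: float = 2.0,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian entries with variance ``k / (fan_in + fan_out)``.

    ``k = 2`` is the rectifier-appropriate gain.
    """
    if fan_in < 1 or fan_out < 1 or k <= 0:
        raise InvalidConfigurationError("fan_in, fan_out >= 1 and k > 0 required")
    rng = rng if rng is not None else np.random.default_rng()
    std = np.sqrt(k / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(fan_in, fan_out))


def initialize(arch: MLPArchitecture, scheme: str,
               rng: np.random.Generator) -> MLPParameters:
    """Initialize weights per scheme; biases start at zero."""
    weights: list[np.ndarray] = []
    biases: list[np.ndarray] = []
    for fan_in, fan_out in zip(arch.layer_sizes, arch.layer_sizes[1:]):
        if scheme == "normal":
            w = init_normal((fan_in, fan_out), rng)
        elif scheme == "orthogonal":
            w = init_orthogonal((fan_in, fan_out), rng)
        elif scheme == "glorot":
            w = init_glorot(fan_in, fan_out, 2.0, rng)
        else:
            raise InvalidConfigurationError(f"unknown init scheme {scheme!r}")
        weights.append(w)
        biases.append(np.zeros(fan_out))
    return MLPParameters(weights, biases)


# ---------------------------------------------------------------------------
# Forward pass, loss, gradients
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(params: MLPParameters, batch: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer, input first, softmax output last."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[1] != params.layer_sizes[0]:
        raise DimensionError(
            f"batch width {batch.shape[1]} != input size {params.layer_sizes[0]}"
        )
    activations = [batch]
    a = batch
    n_layers = len(params.weights)
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w + b
        a = _softmax(z) if i == n_layers - 1 else np.maximum(z, 0.0)
        activations.append(a)
    return activations


def predict(params: MLPParameters, batch: np.ndarray) -> np.ndarray:
    return forward(params, batch)[-1]


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of softmax outputs against int labels."""
    eps = 1e-12
    picked = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(picked + eps)))


def accuracy(params: MLPParameters, dataset: Dataset) -> float:
    """Fraction of samples whose argmax output matches the label.

    Ties break to the lowest class index (NumPy argmax convention).
    """
    if dataset.n_samples == 0:
        raise InvalidConfigurationError("accuracy of an empty dataset is undefined")
    probs = predict(params, dataset.matrix)
    return float(np.mean(np.argmax(probs, axis=1) == dataset.labels))


def _gradients(params: MLPParameters, batch: np.ndarray, labels: np.ndarray
               ) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Backpropagation for softmax + cross-entropy; returns (dW, db, loss)."""
    activations = forward(params, batch)
    probs = activations[-1]
    n = batch.shape[0]
    loss = cross_entropy(probs, labels)
    delta = probs.copy()
    delta[np.arange(n), labels] -= 1.0
    delta /= n
    grads_w: list[np.ndarray] = [None] * len(params.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(params.biases)  # type: ignore
    for i in range(len(params.weights) - 1, -1, -1):
        grads_w[i] = activations[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ params.weights[i].T) * (activations[i] > 0)
    return grads_w, grads_b, loss


def numerical_gradients(params: MLPParameters, batch: np.ndarray,
                        labels: np.ndarray, h: float = 1e-6
                        ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Central finite-difference gradients of the mean cross-entropy.

    Independent check of backpropagation; O(#parameters) forward passes, so
    only usable on tiny networks.
    """
    def loss_at(p: MLPParameters) -> float:
        return cross_entropy(forward(p, batch)[-1], labels)

    grads_w, grads_b = [], []
    for li in range(len(params.weights)):
        gw = np.zeros_like(params.weights[li])
        for idx in np.ndindex(*params.weights[li].shape):
            p = params.copy()
            p.weights[li][idx] += h
            up = loss_at(p)
            p.weights[li][idx] -= 2 * h
            down = loss_at(p)
            gw[idx] = (up - down) / (2 * h)
        grads_w.append(gw)
        gb = np.zeros_like(params.biases[li])
        for j in range(len(params.biases[li])):
            p = params.copy()
            p.biases[li][j] += h
            up = loss_at(p)
            p.biases[li][j] -= 2 * h
            down = loss_at(p)
            gb[j] = (up - down) / (2 * h)
        grads_b.append(gb)
    return grads_w, grads_b


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(arch: MLPArchitecture, dataset: Dataset, config: TrainConfig) -> TrainResult:
    """Mini-batch SGD with Nesterov momentum on categorical cross-entropy.

    Returns initial and final parameter snapshots, per-epoch training
    accuracy/loss, and the first epoch (1-based) at which training accuracy
    hit 1.0, if any.
    """
    if dataset.n_features != arch.layer_sizes[0]:
        raise DimensionError("dataset feature count must equal the input size")
    n_classes = arch.layer_sizes[-1]
    if dataset.labels.min() < 0 or dataset.labels.max() >= n_classes:
        raise DimensionError("labels must be one-hot encodable to the output size")

    rng = np.random.default_rng(config.seed)
    params = initialize(arch, config.init_scheme, rng)
    initial = params.copy()
    vel_w = [np.zeros_like(w) for w in params.weights]
    vel_b = [np.zeros_like(b) for b in params.biases]

    n = dataset.n_samples
    mu = config.momentum
    t = 0  # update counter for the inverse-time decay
    result = TrainResult(initial_params=initial, final_params=params)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            gw, gb, loss = _gradients(params, dataset.matrix[idx],
                                      dataset.labels[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            epoch_losses.append(loss)
            lr_t = config.learning_rate / (1.0 + config.decay * t)
            t += 1
            for i in range(len(params.weights)):
                vel_w[i] = mu * vel_w[i] - lr_t * gw[i]
                params.weights[i] += mu * vel_w[i] - lr_t * gw[i]
                vel_b[i] = mu * vel_b[i] - lr_t * gb[i]
                params.biases[i] += mu * vel_b[i] - lr_t * gb[i]
        acc = accuracy(params, dataset)
        result.accuracy_trace.append(acc)
        result.loss_trace.append(float(np.mean(epoch_losses)))
        result.epochs_run = epoch
        if acc == 1.0 and result.epochs_to_perfect is None:
            result.epochs_to_perfect = epoch
        if config.stop_at_perfect and acc == 1.0:
            break
    result.final_params = params
    return result
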