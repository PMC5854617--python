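"""Three-layer feed-forward sigmoid network for presence/absence prediction.

The architecture is deliberately minimal — one hidden layer, logistic
activations on both hidden and output layers, bias units on both layers —
because that is the standard single-output occurrence model in species
distribution work.  Training is full-batch L-BFGS on either binary
cross-entropy (default: the likelihood of Bernoulli targets with a logistic
output) or squared error, with optional L2 weight decay and seeded random
restarts to tame local minima.

``SigmoidNetClassifier`` wraps the network as a scikit-learn estimator so it
composes with pipelines and model selection; the module-level functions
(``init_network``, ``forward``, ``train``) expose the same machinery
functionally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import ConfigError, DegenerateError, DomainError

__all__ = [
    "NetworkWeights",
    "TrainConfig",
    "init_network",
    "forward",
    "train",
    "SigmoidNetClassifier",
    "sweep_hidden_sizes",
]


@dataclass
class NetworkWeights:
    """All connection weights of one three-layer sigmoid network.

    ``input_to_hidden`` has shape (n_inputs + 1, n_hidden); the last row holds
    the hidden biases.  ``hidden_to_output`` has length n_hidden + 1; the last
    entry is the output bias.
    """

    input_to_hidden: np.ndarray
    hidden_to_output: np.ndarray

    def __post_init__(self) -> None:
        self.input_to_hidden = np.asarray(self.input_to_hidden, dtype=float)
        self.hidden_to_output = np.asarray(self.hidden_to_output, dtype=float)
        if self.input_to_hidden.ndim != 2 or self.hidden_to_output.ndim != 1:
            raise DomainError("weight arrays have wrong rank")
        if self.hidden_to_output.shape[0] != self.input_to_hidden.shape[1] + 1:
            raise DomainError("hidden layer sizes of the two weight blocks disagree")
        if not (
            np.isfinite(self.input_to_hidden).all() and np.isfinite(self.hidden_to_output).all()
        ):
            raise DomainError("weights must be finite")

    @property
    def n_inputs(self) -> int:
        return self.input_to_hidden.shape[0] - 1

    @property
    def n_hidden(self) -> int:
        return self.input_to_hidden.shape[1]

    def to_json_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "n_hidden": self.n_hidden,
            "input_to_hidden": self.input_to_hidden.ravel().tolist(),
            "hidden_to_output": self.hidden_to_output.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "NetworkWeights":
        w = np.asarray(d["input_to_hidden"], dtype=float).reshape(
            d["n_inputs"] + 1, d["n_hidden"]
        )
        return cls(w, np.asarray(d["hidden_to_output"], dtype=float))

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())


@dataclass
class TrainConfig:
    """Training configuration; every unspecified-by-convention knob is exposed."""

    n_hidden: int = 5
    loss: str = "cross_entropy"  # or "squared_error"
    weight_decay: float = 0.0
    max_iterations: int = 2000
    tolerance: float = 1e-8
    init_range: float = 0.5
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ConfigError("n_hidden must be >= 1")
        if self.loss not in ("cross_entropy", "squared_error"):
            raise ConfigError(f"unknown loss {self.loss!r}")
        if self.weight_decay < 0 or self.init_range < 0:
            raise ConfigError("weight_decay and init_range must be nonnegative")
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")


def init_network(
    n_inputs: int, n_hidden: int, init_range: float = 0.5, seed: int = 0
) -> NetworkWeights:
    """Draw all weights uniformly from [-init_range, +init_range], seeded."""
    if n_inputs < 1 or n_hidden < 1:
        raise DomainError("n_inputs and n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-init_range, init_range, size=(n_inputs + 1, n_hidden))
    v = rng.uniform(-init_range, init_range, size=n_hidden + 1)
    return NetworkWeights(w, v)


def _forward_full(weights: NetworkWeights, X: np.ndarray):
    """Return (hidden activations, output logits, output probabilities)."""
    z1 = X @ weights.input_to_hidden[:-1] + weights.input_to_hidden[-1]
    hidden = expit(z1)
    z2 = hidden @ weights.hidden_to_output[:-1] + weights.hidden_to_output[-1]
    return hidden, z2, expit(z2)


def forward(weights: NetworkWeights, x) -> float | np.ndarray:
    """Network output sigma(v . [sigma(W . [x, 1]), 1]) for one row or a matrix."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise DomainError("inputs must be finite")
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != weights.n_inputs:
        raise DomainError(f"expected {weights.n_inputs} inputs, got {X.shape[1]}")
    _, _, p = _forward_full(weights, X)
    return float(p[0]) if single else p


def _pack(weights: NetworkWeights) -> np.ndarray:
    return np.concatenate([weights.input_to_hidden.ravel(), weights.hidden_to_output])


def _unpack(theta: np.ndarray, n_inputs: int, n_hidden: int) -> NetworkWeights:
    split = (n_inputs + 1) * n_hidden
    return NetworkWeights(
        theta[:split].reshape(n_inputs + 1, n_hidden), theta[split:]
    )


def loss_and_gradient(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    loss: str = "cross_entropy",
    weight_decay: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Mean loss plus L2 penalty, and its analytic gradient (backprop)."""
    n, n_inputs = X.shape
    weights = _unpack(theta, n_inputs, n_hidden)
    hidden, z2, p = _forward_full(weights, X)
    if loss == "cross_entropy":
        # log(1 + e^z) - y z, computed stably
        value = float(np.mean(np.logaddexp(0.0, z2) - y * z2))
        dz2 = (p - y) / n
    else:
        value = float(np.mean((p - y) ** 2))
        dz2 = 2.0 * (p - y) * p * (1.0 - p) / n
    value += weight_decay * float(theta @ theta)

    v = weights.hidden_to_output
    grad_v = np.concatenate([hidden.T @ dz2, [dz2.sum()]])
    dhidden = np.outer(dz2, v[:-1]) * hidden * (1.0 - hidden)
    grad_w = np.vstack([X.T @ dhidden, dhidden.sum(axis=0)])
    grad = np.concatenate([grad_w.ravel(), grad_v]) + 2.0 * weight_decay * theta
    return value, grad


def train(x_table, y, config: TrainConfig) -> NetworkWeights:
    """Train a network, keeping the best final loss over seeded restarts."""
    X = np.asarray(x_table, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DomainError("x_table rows must match y length")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise DomainError("targets must be binary 0/1")
    if classes.size < 2:
        raise DegenerateError("targets contain a single class; nothing to learn")

    seeds = np.random.SeedSequence(config.seed).generate_state(config.restarts)
    best: tuple[float, NetworkWeights] | None = None
    for s in seeds:
        w0 = init_network(X.shape[1], config.n_hidden, config.init_range, int(s))
        res = minimize(
            loss_and_gradient,
            _pack(w0),
            args=(X, y, config.n_hidden, config.loss, config.weight_decay),
            method="L-BFGS-B",
            jac=True,
            options={
                "maxiter": config.max_iterations,
                "ftol": config.tolerance,
                "gtol": 1e-7,
            },
        )
        if best is None or res.fun < best[0]:
            best = (float(res.fun), _unpack(res.x, X.shape[1], config.n_hidden))
    assert best is not None
    return best[1]


class SigmoidNetClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator face of the three-layer sigmoid network.

    Parameters mirror :class:`TrainConfig`; ``random_state`` seeds both the
    restart initializations and nothing else.  ``predict`` thresholds the
    positive-class probability at ``cutoff`` (default 0.5 — occurrence work
    normally re-derives the cutoff from a ROC curve afterwards).

    Attributes (after ``fit``): ``classes_``, ``network_`` (NetworkWeights),
    ``loss_`` (best final training loss), ``n_features_in_``.
    """

    def __init__(
        self,
        n_hidden: int = 5,
        loss: str = "cross_entropy",
        weight_decay: float = 0.0,
        max_iter: int = 2000,
        tol: float = 1e-8,
        init_range: float = 0.5,
        restarts: int = 5,
        cutoff: float = 0.5,
        random_state: int = 0,
    ) -> None:
        self.n_hidden = n_hidden
        self.loss = loss
        self.weight_decay = weight_decay
        self.max_iter = max_iter
        self.tol = tol
        self.init_range = init_range
        self.restarts = restarts
        self.cutoff = cutoff
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            n_hidden=self.n_hidden,
            loss=self.loss,
            weight_decay=self.weight_decay,
            max_iterations=self.max_iter,
            tolerance=self.tol,
            init_range=self.init_range,
            restarts=self.restarts,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if self.classes_.shape[0] != 2:
            raise DegenerateError(
                f"expected exactly two classes, got {self.classes_.tolist()}"
            )
        y01 = (y == self.classes_[1]).astype(float)
        self.network_ = train(X, y01, self._config())
        self.loss_ = loss_and_gradient(
            _pack(self.network_), X, y01, self.n_hidden, self.loss, self.weight_decay
        )[0]
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X)
        p = forward(self.network_, X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.cutoff).astype(int)]

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]


def sweep_hidden_sizes(
    data,
    target: str,
    sizes=range(1, 16),
    config: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    cutoff_mode: str = "test",
):
    """Choose the hidden-layer size by median cross-validated kappa.

    Each candidate size is scored with a full k-fold cross-validation; the
    size with the highest median kappa wins, ties broken toward fewer hidden
    neurons.  Returns ``(best TrainConfig, per-size table)`` where the table
    is a list of ``(size, median kappa)`` pairs.
    """
    from .cascade import environment_model_factory
    from .evaluation import cross_validate

    sizes = list(sizes)
    if not sizes:
        raise ConfigError("no candidate sizes supplied")
    config = config or TrainConfig()
    table: list[tuple[int, float]] = []
    for size in sizes:
        cfg = replace(config, n_hidden=size)
        report = cross_validate(
            data,
            target,
            environment_model_factory(target, cfg),
            folds=folds,
            seed=seed,
            cutoff_mode=cutoff_mode,
        )
        table.append((size, report.median_k))
    best_size = max(table, key=lambda t: (t[1], -t[0]))[0]
    return replace(config, n_hidden=best_size), table
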