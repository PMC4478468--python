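"""A small fully-connected sigmoid network trained by backprop with momentum.

Every property predictor in this package is one or two of these networks.
The training scheme is the classic one: stochastic per-example updates in a
seeded shuffled order, mean-squared-error loss, and a momentum term on each
weight update.  Defaults follow the hyperparameters that work well for the
structural-property task (learning rate 0.001, momentum 0.85, sigmoid
activations on hidden and output layers); anything larger-scale than that —
minibatching, adaptive rates, early stopping — is deliberately out of scope
so that runs stay exactly reproducible from (seed, data, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

INIT_RANGE = 0.5  # uniform weight init in [-0.5, 0.5]


@dataclass
class NetworkSpec:
    """Architecture and training hyperparameters.

    ``layer_sizes`` lists input, hidden... and output widths and must have
    at least two entries.
    """

    layer_sizes: tuple[int, ...]
    seed: int = 0
    learning_rate: float = 0.001
    momentum: float = 0.85

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(n) for n in self.layer_sizes)
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        if any(n < 1 for n in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class Network:
    """Weights and biases realizing a :class:`NetworkSpec`."""

    spec: NetworkSpec
    weights: list[np.ndarray] = field(default_factory=list)  # (out, in)
    biases: list[np.ndarray] = field(default_factory=list)  # (out,)
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.spec.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.spec.layer_sizes[-1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Propagate one input vector; every layer is affine + sigmoid."""
        a = np.asarray(x, dtype=float)
        if a.shape != (self.n_inputs,):
            raise ValueError(
                f"input shape {a.shape} != ({self.n_inputs},)"
            )
        for W, b in zip(self.weights, self.biases):
            a = _sigmoid(W @ a + b)
        return a

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        """Vectorized forward pass over rows of ``X``."""
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[1] != self.n_inputs:
            raise ValueError(f"input shape {A.shape} incompatible")
        for W, b in zip(self.weights, self.biases):
            A = _sigmoid(A @ W.T + b)
        return A

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "layer_sizes": list(self.spec.layer_sizes),
            "seed": self.spec.seed,
            "learning_rate": self.spec.learning_rate,
            "momentum": self.spec.momentum,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        })

    @classmethod
    def from_json(cls, text: str) -> "Network":
        d = json.loads(text)
        spec = NetworkSpec(
            layer_sizes=tuple(d["layer_sizes"]), seed=d["seed"],
            learning_rate=d["learning_rate"], momentum=d["momentum"],
        )
        return cls(
            spec=spec,
            weights=[np.array(w) for w in d["weights"]],
            biases=[np.array(b) for b in d["biases"]],
        )


def init_network(spec: NetworkSpec) -> Network:
    """Seeded symmetric-uniform weight initialization."""
    rng = np.random.default_rng(spec.seed)
    weights, biases = [], []
    for n_in, n_out in zip(spec.layer_sizes, spec.layer_sizes[1:]):
        weights.append(rng.uniform(-INIT_RANGE, INIT_RANGE, (n_out, n_in)))
        biases.append(rng.uniform(-INIT_RANGE, INIT_RANGE, n_out))
    return Network(spec=spec, weights=weights, biases=biases)


def gradients(net: Network, x: np.ndarray, y: np.ndarray
              ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backprop gradients of the per-example MSE ``mean((out - y)^2)``."""
    activations = [np.asarray(x, dtype=float)]
    a = activations[0]
    for W, b in zip(net.weights, net.biases):
        a = _sigmoid(W @ a + b)
        activations.append(a)
    out = activations[-1]
    # dL/dout for L = mean squared error over output nodes
    delta = (2.0 / net.n_outputs) * (out - y) * out * (1.0 - out)
    grads_w: list[np.ndarray] = [None] * len(net.weights)
    grads_b: list[np.ndarray] = [None] * len(net.weights)
    for layer in range(len(net.weights) - 1, -1, -1):
        grads_w[layer] = np.outer(delta, activations[layer])
        grads_b[layer] = delta
        if layer > 0:
            a_prev = activations[layer]
            delta = (net.weights[layer].T @ delta) * a_prev * (1.0 - a_prev)
    return grads_w, grads_b


def train(net: Network, X: np.ndarray, Y: np.ndarray, epochs: int,
          shuffle_seed: int | None = None) -> Network:
    """Train in place with per-example updates and momentum; returns ``net``.

    Presentation order is reshuffled every epoch by a generator seeded from
    ``shuffle_seed`` (defaults to the spec seed), so the whole run is a
    deterministic function of (weights, data, seeds).  Mean squared error
    over the full set is appended to ``net.loss_history`` after each epoch;
    a non-finite loss aborts with a diagnostic.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    if X.shape[1] != net.n_inputs or Y.shape[1] != net.n_outputs:
        raise ValueError("data widths do not match the network")
    if np.any(Y < 0) or np.any(Y > 1):
        raise ValueError("targets must lie in [0, 1] for sigmoid outputs")
    if epochs == 0:
        return net
    rng = np.random.default_rng(
        net.spec.seed if shuffle_seed is None else shuffle_seed
    )
    lr, mom = net.spec.learning_rate, net.spec.momentum
    vel_w = [np.zeros_like(w) for w in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for idx in order:
            gw, gb = gradients(net, X[idx], Y[idx])
            for layer in range(len(net.weights)):
                vel_w[layer] = mom * vel_w[layer] - lr * gw[layer]
                vel_b[layer] = mom * vel_b[layer] - lr * gb[layer]
                net.weights[layer] += vel_w[layer]
                net.biases[layer] += vel_b[layer]
        loss = float(np.mean((net.forward_batch(X) - Y) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged: loss {loss} after epoch "
                f"{len(net.loss_history) + 1}"
            )
        net.loss_history.append(loss)
    return net
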