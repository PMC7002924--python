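"""Layer-wise relevance propagation through dense feedforward networks.

Given a trained network with input X, true labels T and output T', the
output-layer relevance is initialized as R_i = T_i * T'_i and propagated
backward layer by layer with the rule

    R_j = sum_k  z_jk / (eps * sign(s_k) + s_k) * R_k,    s_k = sum_j z_jk

where z_jk depends on the propagation rule:

    z+   (unbounded layers):      z_jk = a_j * max(0, w_jk)
    zB   (bounded layers, e.g. an input scaled to [l, h]):
                                  z_jk = a_j*w_jk - l_j*max(0,w_jk) - h_j*min(0,w_jk)

a_j are the forward activations entering the layer, eps (default 1e-9)
stabilizes near-zero denominators, and biases receive no relevance.  For
ReLU networks this is the deep Taylor decomposition.  Because z+ redistributes
relevance proportionally, the total is conserved per layer in the eps -> 0
limit when all z_jk are nonnegative.

Relevance is per sample, so a feature's importance can be resolved per
simulation frame — the property that distinguishes LRP-based estimators
from the global ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax

__all__ = [
    "Layer",
    "NetworkSpec",
    "relevance_init",
    "propagate_layer",
    "lrp",
    "average_relevance",
]

_ACTIVATIONS = {
    "relu": lambda z: np.maximum(z, 0.0),
    "logistic": expit,
    "identity": lambda z: z,
    "softmax": lambda z: softmax(z, axis=-1),
}


@dataclass
class Layer:
    weights: np.ndarray  # (n_in, n_out)
    bias: np.ndarray  # (n_out,)
    activation: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.weights.shape[1] != self.bias.shape[0]:
            raise ValueError("weight/bias shape mismatch")


@dataclass
class NetworkSpec:
    """An ordered stack of dense layers plus optional input bounds.

    ``input_bounds = (l, h)`` (scalars or per-input vectors) marks the
    input layer as bounded, switching its backward rule from z+ to zB.
    """

    layers: list[Layer]
    input_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for a, b in zip(self.layers, self.layers[1:]):
            if a.weights.shape[1] != b.weights.shape[0]:
                raise ValueError("adjacent layer dimensions inconsistent")
        if self.input_bounds is not None:
            n_in = self.layers[0].weights.shape[0]
            l = np.broadcast_to(np.asarray(self.input_bounds[0], dtype=float), (n_in,)).copy()
            h = np.broadcast_to(np.asarray(self.input_bounds[1], dtype=float), (n_in,)).copy()
            if np.any(l > h):
                raise ValueError("input lower bound exceeds upper bound")
            self.input_bounds = (l, h)

    @property
    def n_inputs(self) -> int:
        return self.layers[0].weights.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.layers[-1].weights.shape[1]

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer, input first, output last."""
        a = np.asarray(X, dtype=float)
        if a.ndim == 1:
            a = a[None, :]
        activations = [a]
        for layer in self.layers:
            a = _ACTIVATIONS[layer.activation](a @ layer.weights + layer.bias)
            activations.append(a)
        return activations

    # -- sklearn adapters ------------------------------------------------

    @classmethod
    def from_sklearn_mlp(cls, model, output_activation: str, input_bounds=None) -> "NetworkSpec":
        """Wrap a fitted MLPClassifier/MLPRegressor.

        ``output_activation`` is 'softmax' for classifiers and 'identity'
        for regressors; hidden layers take the model's activation.
        """
        layers = []
        n = len(model.coefs_)
        for i, (w, b) in enumerate(zip(model.coefs_, model.intercepts_)):
            act = output_activation if i == n - 1 else model.activation
            layers.append(Layer(w, b, act))
        return cls(layers, input_bounds)

    @classmethod
    def from_sklearn_rbm(cls, model, input_bounds=(0.0, 1.0)) -> "NetworkSpec":
        """Wrap a fitted BernoulliRBM as a single logistic layer
        (visible -> hidden activation probabilities)."""
        return cls(
            [Layer(model.components_.T, model.intercept_hidden_, "logistic")], input_bounds
        )

    # -- JSON round trip (test fixtures) ---------------------------------

    def to_json(self) -> str:
        doc = {
            "layers": [
                {"weights": l.weights.tolist(), "bias": l.bias.tolist(), "activation": l.activation}
                for l in self.layers
            ],
            "input_bounds": None
            if self.input_bounds is None
            else [self.input_bounds[0].tolist(), self.input_bounds[1].tolist()],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        doc = json.loads(text)
        layers = [Layer(np.array(l["weights"]), np.array(l["bias"]), l["activation"]) for l in doc["layers"]]
        bounds = doc["input_bounds"]
        if bounds is not None:
            bounds = (np.array(bounds[0]), np.array(bounds[1]))
        return cls(layers, bounds)


def relevance_init(output: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Output-layer relevance R_i = T_i * T'_i.

    ``target`` is the one-hot label for classifiers, or a ones mask for
    reconstruction networks where every output contributes.
    """
    output = np.asarray(output, dtype=float)
    target = np.asarray(target, dtype=float)
    if output.shape != target.shape:
        raise ValueError("output/target length mismatch")
    return output * target


def _stabilized(s: np.ndarray, epsilon: float) -> np.ndarray:
    if epsilon == 0 and np.any(s == 0):
        raise ZeroDivisionError(
            "all-zero denominator in relevance redistribution; use epsilon > 0"
        )
    return s + epsilon * np.where(s >= 0, 1.0, -1.0)


def propagate_layer(
    R_k: np.ndarray,
    a_j: np.ndarray,
    w: np.ndarray,
    rule: str = "zplus",
    epsilon: float = 1e-9,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Propagate relevance one layer down.

    ``R_k``: (n, K) upper-layer relevance; ``a_j``: (n, J) lower-layer
    activations; ``w``: (J, K) weights.  Implemented with matrix products
    rather than the explicit z_jk tensor: s_k = sum_j z_jk, then
    R_j = sum_k z_jk * R_k / (s_k + eps*sign(s_k)).
    """
    R_k = np.atleast_2d(np.asarray(R_k, dtype=float))
    a_j = np.atleast_2d(np.asarray(a_j, dtype=float))
    w = np.asarray(w, dtype=float)
    wp = np.maximum(w, 0.0)
    if rule == "zplus":
        s = a_j @ wp
        ratio = R_k / _stabilized(s, epsilon)
        return a_j * (ratio @ wp.T)
    if rule == "zB":
        if bounds is None:
            raise ValueError("zB rule requires input bounds")
        l, h = (np.asarray(b, dtype=float) for b in bounds)
        wm = np.minimum(w, 0.0)
        s = a_j @ w - l @ wp - h @ wm
        ratio = R_k / _stabilized(s, epsilon)
        return a_j * (ratio @ w.T) - l * (ratio @ wp.T) - h * (ratio @ wm.T)
    raise ValueError(f"unknown rule {rule!r}")


def lrp(
    net: NetworkSpec,
    X: np.ndarray,
    targets: np.ndarray | None = None,
    epsilon: float = 1e-9,
) -> np.ndarray:
    """Per-sample, per-input relevance for the samples in X.

    ``targets``: per-sample mask at the output layer (one-hot rows for
    classifiers; omitted -> ones, i.e. all outputs contribute, as for
    autoencoders).  Hidden layers use z+; the input layer uses zB when the
    network declares input bounds.  Returns an (n_samples, n_inputs)
    array of unnormalized relevance.
    """
    activations = net.forward(X)
    output = activations[-1]
    if targets is None:
        targets = np.ones_like(output)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    R = relevance_init(output, targets)
    for i in range(len(net.layers) - 1, -1, -1):
        a_j = activations[i]
        if i == 0 and net.input_bounds is not None:
            R = propagate_layer(R, a_j, net.layers[i].weights, "zB", epsilon, net.input_bounds)
        else:
            R = propagate_layer(R, a_j, net.layers[i].weights, "zplus", epsilon)
    return R


def average_relevance(per_sample: np.ndarray) -> np.ndarray:
    """Mean relevance over samples, normalized to an upper bound of 1.

    Divides by the maximum entry; if the maximum positive value is 0 but
    negative relevance exists (mixed-sign masks), divides by max |value|.
    An all-zero mean is returned unchanged.
    """
    per_sample = np.atleast_2d(np.asarray(per_sample, dtype=float))
    if per_sample.shape[0] < 1:
        raise ValueError("need at least one sample")
    mean = per_sample.mean(axis=0)
    top = mean.max()
    if top <= 0:
        top = np.abs(mean).max()
    return mean / top if top > 0 else mean
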