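"""Minimal dense-network core with manual backpropagation.

All neural components of the pipeline (conditional autoencoder, WGAN-GP
generator and critic, MLP classifier) are fully-connected ReLU networks, so a
compact numpy implementation with analytic gradients is sufficient and keeps
training bit-reproducible under a fixed seed.

The one non-standard piece is the double-backward needed by the WGAN-GP
gradient penalty: the penalty depends on the norm of the critic's gradient
with respect to its *input*, so its parameter gradient requires
differentiating that input-gradient.  For ReLU networks the activation's
second derivative vanishes almost everywhere, which makes the input-gradient a
(mask-gated) linear function of the weights; :func:`gp_weight_grads`
implements the resulting exact chain rule and is validated against a
finite-difference oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Net",
    "init_net",
    "forward",
    "backward",
    "input_gradient",
    "gp_weight_grads",
    "Adam",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class Net:
    """A fully-connected network: ReLU hidden layers, configurable output.

    ``weights[i]`` has shape ``(d_in, d_out)`` for layer ``i``; rows of the
    data matrix are samples.  ``output`` is ``"linear"`` or ``"sigmoid"``.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    output: str = "linear"

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def dims(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def copy(self) -> "Net":
        return Net(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.output,
        )

    def params(self) -> list[np.ndarray]:
        return list(self.weights) + list(self.biases)


def init_net(dims: list[int], rng: np.random.Generator, output: str = "linear") -> Net:
    """He-initialised network with layer widths ``dims``."""
    if len(dims) < 2:
        raise ValueError("need at least input and output dims")
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return Net(weights, biases, output)


def forward(net: Net, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Forward pass; returns activated output and a cache for backward."""
    a = np.asarray(x, dtype=float)
    acts = [a]
    masks = []
    L = net.n_layers
    for i in range(L):
        z = a @ net.weights[i] + net.biases[i]
        if i < L - 1:
            mask = z > 0
            a = z * mask
            masks.append(mask)
        else:
            a = sigmoid(z) if net.output == "sigmoid" else z
    acts_cache = {"acts": acts + [a], "masks": masks, "inputs": None}
    # store per-layer inputs (post-activation of previous layer)
    layer_inputs = [acts[0]]
    h = acts[0]
    for i in range(L - 1):
        h = (h @ net.weights[i] + net.biases[i]) * masks[i]
        layer_inputs.append(h)
    acts_cache["inputs"] = layer_inputs
    return a, acts_cache


def backward(net: Net, cache: dict, dz_out: np.ndarray) -> tuple[list, list, np.ndarray]:
    """Backpropagate ``dz_out`` (gradient w.r.t. the output *pre-activation*).

    Callers fold the output activation into ``dz_out``: for sigmoid + BCE the
    clean form is ``(p - t) / n``.  Returns (weight grads, bias grads, dx).
    """
    L = net.n_layers
    inputs, masks = cache["inputs"], cache["masks"]
    gw = [None] * L
    gb = [None] * L
    delta = np.asarray(dz_out, dtype=float)
    for i in range(L - 1, -1, -1):
        gw[i] = inputs[i].T @ delta
        gb[i] = delta.sum(axis=0)
        delta = delta @ net.weights[i].T
        if i > 0:
            delta = delta * masks[i - 1]
    return gw, gb, delta


def input_gradient(net: Net, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Per-row gradient of a scalar-output (linear) network w.r.t. its input.

    Returns ``g`` of shape ``(n, d_in)`` and a cache (ReLU masks plus the
    backward signals ``delta_i`` = d f / d z_i) reused by
    :func:`gp_weight_grads`.
    """
    if net.output != "linear" or net.weights[-1].shape[1] != 1:
        raise ValueError("input_gradient expects a scalar linear-output net")
    _, cache = forward(net, x)
    masks = cache["masks"]
    n = x.shape[0]
    L = net.n_layers
    deltas = [None] * L  # deltas[i] = d f / d z_{i+1}, shape (n, d_i)
    delta = np.ones((n, 1))
    deltas[L - 1] = delta
    for i in range(L - 1, 0, -1):
        delta = (delta @ net.weights[i].T) * masks[i - 1]
        deltas[i - 1] = delta
    g = delta @ net.weights[0].T
    return g, {"masks": masks, "deltas": deltas}


def gp_weight_grads(net: Net, gcache: dict, v: np.ndarray) -> list[np.ndarray]:
    """Gradient of a penalty P(g) w.r.t. the weights, given ``v = dP/dg``.

    ``g`` is the input-gradient from :func:`input_gradient`.  With ReLU masks
    held fixed (exact a.e.), ``g = delta_1 W_1^T`` with
    ``delta_{i-1} = (delta_i W_i^T) * M_{i-1}``, so each weight matrix enters
    the chain linearly and the chain rule gives
    ``dP/dW_i = u_{i-1}^T delta_i`` with ``u_0 = v`` and
    ``u_i = (u_{i-1} W_i) * M_i``.  Biases receive no gradient.
    """
    masks, deltas = gcache["masks"], gcache["deltas"]
    L = net.n_layers
    gw = []
    u = np.asarray(v, dtype=float)
    for i in range(L):
        gw.append(u.T @ deltas[i])
        if i < L - 1:
            u = (u @ net.weights[i]) * masks[i]
    return gw


@dataclass
class Adam:
    """Adam optimiser over a flat list of parameter arrays (in-place update)."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list = field(default_factory=list)
    _v: list = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
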