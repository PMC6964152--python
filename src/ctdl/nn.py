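"""Feed-forward value networks with bespoke backpropagation.

The "neocortical" half of the model: a small fully connected network with
rectified-linear hidden layers and a linear output layer, trained by
gradient descent on the mean squared TD error. Gradients are computed by
hand-rolled reverse-mode differentiation so the package has no autodiff
dependency; RMSProp (the Q-learning configuration) and Adam (the
actor-critic configuration) are implemented against the same parameter
structure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "TrainingBatch", "RMSProp", "Adam", "sync_target"]


@dataclass
class TrainingBatch:
    """Inputs, scalar regression targets, and the output index each target
    applies to (non-selected outputs get zero gradient from that sample)."""

    inputs: np.ndarray          # (B, in_dim)
    targets: np.ndarray         # (B,)
    selected_outputs: np.ndarray  # (B,) int

    def __post_init__(self):
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        self.selected_outputs = np.asarray(self.selected_outputs, dtype=int).ravel()
        if not (len(self.inputs) == len(self.targets) == len(self.selected_outputs)):
            raise ValueError("batch fields must have equal length")


class MLP:
    """Multilayer perceptron: linear layers, ReLU hidden, identity output."""

    def __init__(self, layer_sizes: list[int], rng: np.random.Generator | None = None,
                 zero_init: bool = False, output_scale: float = 1.0):
        """``output_scale`` multiplies the final layer's init bound; the value
        agents use 0.0 so a fresh network predicts exactly zero everywhere
        (bootstrapped targets then start from r rather than from the maximum
        of a random function, whose positive bias is amplified by gamma-max
        bootstrapping)."""
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        if any(s <= 0 for s in layer_sizes):
            raise ValueError("layer sizes must be positive")
        self.layer_sizes = list(layer_sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        last = len(layer_sizes) - 2
        for i, (fan_in, fan_out) in enumerate(zip(layer_sizes[:-1], layer_sizes[1:])):
            bound = 1.0 / np.sqrt(fan_in)
            if i == last:
                bound *= output_scale
            if zero_init or bound == 0.0:
                w = np.zeros((fan_in, fan_out))
            else:
                if rng is None:
                    raise ValueError("a seeded numpy Generator is required")
                w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))

    @property
    def in_dim(self) -> int:
        return self.layer_sizes[0]

    @property
    def out_dim(self) -> int:
        return self.layer_sizes[-1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the network; accepts a single vector or a (B, in) batch."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        h = np.atleast_2d(x)
        if h.shape[1] != self.in_dim:
            raise ValueError(f"input dim {h.shape[1]} != expected {self.in_dim}")
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        out = h @ self.weights[-1] + self.biases[-1]
        return out[0] if single else out

    def _forward_cached(self, x: np.ndarray):
        acts = [np.atleast_2d(np.asarray(x, dtype=float))]
        h = acts[0]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return out, acts

    def backward(self, x: np.ndarray, dout: np.ndarray):
        """Gradients of a scalar loss given dloss/doutput for each sample.

        Returns (grad_weights, grad_biases) matching the parameter lists.
        """
        out, acts = self._forward_cached(x)
        dout = np.atleast_2d(np.asarray(dout, dtype=float))
        gw = [np.empty_like(w) for w in self.weights]
        gb = [np.empty_like(b) for b in self.biases]
        delta = dout
        for layer in reversed(range(len(self.weights))):
            gw[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        return gw, gb

    def gradients(self, batch: TrainingBatch):
        """Gradients of mean_i (y_i - out_i[k_i])^2 over the batch."""
        out, acts = self._forward_cached(batch.inputs)
        B = len(batch.targets)
        if batch.selected_outputs.max(initial=0) >= self.out_dim or \
           batch.selected_outputs.min(initial=0) < 0:
            raise IndexError("selected output index out of range")
        pred = out[np.arange(B), batch.selected_outputs]
        dout = np.zeros_like(out)
        dout[np.arange(B), batch.selected_outputs] = -2.0 * (batch.targets - pred) / B
        gw = [np.empty_like(w) for w in self.weights]
        gb = [np.empty_like(b) for b in self.biases]
        delta = dout
        for layer in reversed(range(len(self.weights))):
            gw[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        return gw, gb

    def loss(self, batch: TrainingBatch) -> float:
        out = np.atleast_2d(self.forward(batch.inputs))
        pred = out[np.arange(len(batch.targets)), batch.selected_outputs]
        return float(np.mean((batch.targets - pred) ** 2))


def sync_target(online: MLP) -> MLP:
    """Deep copy of the online network; later online updates leave it fixed."""
    return copy.deepcopy(online)


class RMSProp:
    """RMSProp with a running squared-gradient cache.

    update: cache <- kappa*cache + (1-kappa)*g^2;
            param <- param - lr*g / (sqrt(cache) + denom_const)
    """

    def __init__(self, net: MLP, lr: float = 0.00025, kappa: float = 0.95,
                 denom_const: float = 0.01):
        self.lr, self.kappa, self.denom_const = lr, kappa, denom_const
        self.cache_w = [np.zeros_like(w) for w in net.weights]
        self.cache_b = [np.zeros_like(b) for b in net.biases]

    def step(self, net: MLP, gw, gb) -> None:
        for i in range(len(net.weights)):
            if not (np.all(np.isfinite(gw[i])) and np.all(np.isfinite(gb[i]))):
                raise FloatingPointError("non-finite gradient: training diverged")
            self.cache_w[i] = self.kappa * self.cache_w[i] + (1 - self.kappa) * gw[i] ** 2
            self.cache_b[i] = self.kappa * self.cache_b[i] + (1 - self.kappa) * gb[i] ** 2
            net.weights[i] -= self.lr * gw[i] / (np.sqrt(self.cache_w[i]) + self.denom_const)
            net.biases[i] -= self.lr * gb[i] / (np.sqrt(self.cache_b[i]) + self.denom_const)


class Adam:
    """Adam with bias-corrected first and second moments."""

    def __init__(self, net: MLP, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m_w = [np.zeros_like(w) for w in net.weights]
        self.v_w = [np.zeros_like(w) for w in net.weights]
        self.m_b = [np.zeros_like(b) for b in net.biases]
        self.v_b = [np.zeros_like(b) for b in net.biases]

    def step(self, net: MLP, gw, gb) -> None:
        self.t += 1
        c1 = 1 - self.beta1 ** self.t
        c2 = 1 - self.beta2 ** self.t
        for i in range(len(net.weights)):
            if not (np.all(np.isfinite(gw[i])) and np.all(np.isfinite(gb[i]))):
                raise FloatingPointError("non-finite gradient: training diverged")
            self.m_w[i] = self.beta1 * self.m_w[i] + (1 - self.beta1) * gw[i]
            self.v_w[i] = self.beta2 * self.v_w[i] + (1 - self.beta2) * gw[i] ** 2
            self.m_b[i] = self.beta1 * self.m_b[i] + (1 - self.beta1) * gb[i]
            self.v_b[i] = self.beta2 * self.v_b[i] + (1 - self.beta2) * gb[i] ** 2
            net.weights[i] -= self.lr * (self.m_w[i] / c1) / (np.sqrt(self.v_w[i] / c2) + self.eps)
            net.biases[i] -= self.lr * (self.m_b[i] / c1) / (np.sqrt(self.v_b[i] / c2) + self.eps)
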