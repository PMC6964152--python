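"""TD-error-gated self-organizing map memory.

The "hippocampal" half of the model: a square lattice of units, each with
a weight vector beta_u living in normalized [0,1] state space and a value
record — a vector Q(u, a) over actions, or a scalar V(u) in critic mode.

Plasticity is gated by the TD error of the network half. The gain

    delta = 1 - exp(-|td| / tau_delta)     in [0, 1)

scales both the SOM learning rate and the width of the lattice
neighbourhood, so the map only moves when the network is surprised. The
fusion weight

    eta = exp(-tau_eta * d)                in (0, 1]

decays with the euclidean distance d between the normalized state and its
best-matching unit, and sets the SOM's share in the fused value estimate.
"""

from __future__ import annotations

import json

import numpy as np

from .nn import TrainingBatch

__all__ = ["RangeNormalizer", "SOMMemory", "eta_weight", "delta_gain"]


class RangeNormalizer:
    """Online per-dimension min/max record mapping states into [0,1].

    A dimension whose range is still degenerate (min == max) maps to 0.5.
    """

    def __init__(self, dim: int):
        self.low = np.full(dim, np.inf)
        self.high = np.full(dim, -np.inf)

    @property
    def dim(self) -> int:
        return len(self.low)

    def observe(self, state: np.ndarray) -> None:
        state = np.asarray(state, dtype=float)
        if not np.all(np.isfinite(state)):
            raise ValueError("non-finite state")
        self.low = np.minimum(self.low, state)
        self.high = np.maximum(self.high, state)

    def normalize(self, state: np.ndarray, update: bool = True) -> np.ndarray:
        """Map ``state`` into [0,1]^d, first widening the bounds to cover it
        unless ``update`` is false (used when peeking at next states)."""
        state = np.asarray(state, dtype=float)
        if update:
            self.observe(state)
        span = self.high - self.low
        out = np.full(self.dim, 0.5)
        ok = span > 0
        out[ok] = (np.clip(state, self.low, self.high)[ok] - self.low[ok]) / span[ok]
        return out

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        """Inverse map; degenerate dimensions return the single observed value
        (or 0 if nothing was observed). Accepts a vector or a (B, d) batch."""
        z = np.asarray(z, dtype=float)
        span = self.high - self.low
        base = np.where(np.isfinite(self.low), self.low, 0.0)
        return np.where(span > 0, base + z * span, base)

    def state_dict(self) -> dict:
        return {"low": self.low.tolist(), "high": self.high.tolist()}

    @classmethod
    def from_state_dict(cls, d: dict) -> "RangeNormalizer":
        n = cls(len(d["low"]))
        n.low = np.asarray(d["low"], dtype=float)
        n.high = np.asarray(d["high"], dtype=float)
        return n


def eta_weight(distance: float, tau_eta: float, squared: bool = False) -> float:
    """Fusion weight eta = exp(-tau_eta * d) (or exp(-tau_eta * d^2))."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    d = distance * distance if squared else distance
    return float(np.exp(-tau_eta * d))


def delta_gain(td_error: float, tau_delta: float) -> float:
    """Plasticity gain delta = 1 - exp(-|td|/tau_delta), in [0, 1)."""
    return float(1.0 - np.exp(-abs(td_error) / tau_delta))


class SOMMemory:
    """Square-lattice SOM with per-unit value records.

    Parameters follow the model's published configuration: ``tau_eta``
    scales the BMU distance in the fusion weight, ``tau_delta`` scales the
    TD error in the plasticity gain, ``sigma``/``sigma_const`` set the
    TD-modulated neighbourhood width, ``alpha`` is the weight learning
    rate and ``rho`` the value learning rate.
    """

    def __init__(self, n_units: int, state_dim: int, n_actions: int | None,
                 rng: np.random.Generator, tau_eta: float = 10.0,
                 tau_delta: float = 1.0, sigma: float = 0.1,
                 sigma_const: float = 0.1, alpha: float = 0.01,
                 rho: float = 0.9, eta_squared: bool = False):
        side = int(round(np.sqrt(n_units)))
        if side * side != n_units:
            raise ValueError(f"n_units={n_units} is not a square lattice size")
        self.side = side
        self.n_units = n_units
        self.state_dim = state_dim
        self.n_actions = n_actions  # None => scalar critic mode V(u)
        self.tau_eta, self.tau_delta = tau_eta, tau_delta
        self.sigma, self.sigma_const = sigma, sigma_const
        self.alpha, self.rho = alpha, rho
        self.eta_squared = eta_squared
        xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        self.unit_positions = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
        self.unit_weights = rng.uniform(0.0, 1.0, size=(n_units, state_dim))
        shape = (n_units,) if n_actions is None else (n_units, n_actions)
        self.values = np.zeros(shape)

    # -- retrieval ---------------------------------------------------------

    def best_matching_unit(self, s_norm: np.ndarray) -> tuple[int, float]:
        """Argmin over units of ||beta_u - s||; ties go to the lowest index."""
        s_norm = np.asarray(s_norm, dtype=float)
        if s_norm.shape != (self.state_dim,):
            raise ValueError("state dimension mismatch")
        dists = np.linalg.norm(self.unit_weights - s_norm, axis=1)
        bmu = int(np.argmin(dists))  # np.argmin returns the first minimum
        return bmu, float(dists[bmu])

    def eta(self, distance: float) -> float:
        return eta_weight(distance, self.tau_eta, squared=self.eta_squared)

    def delta(self, td_error: float) -> float:
        return delta_gain(td_error, self.tau_delta)

    # -- learning ----------------------------------------------------------

    def weight_update(self, s_norm: np.ndarray, bmu: int, delta: float) -> None:
        """Move units toward ``s_norm`` with TD-gated rate and width.

        beta_u += alpha * delta * phi(u) * (s - beta_u), with lattice kernel
        phi(u) = exp(-||p_u - p_bmu||^2 / (2 (delta*sigma + sigma_const)^2)).
        delta = 0 leaves the map untouched.
        """
        if delta == 0.0:
            return
        width = delta * self.sigma + self.sigma_const
        sq = np.sum((self.unit_positions - self.unit_positions[bmu]) ** 2, axis=1)
        phi = np.exp(-sq / (2.0 * width * width))
        step = (self.alpha * delta) * phi[:, None]
        self.unit_weights += step * (np.asarray(s_norm, dtype=float) - self.unit_weights)

    def value_update(self, unit: int, action: int | None, target: float,
                     eta_prev: float) -> None:
        """value <- value + rho * eta_prev * (target - value).

        ``action`` is required in Q mode and ignored in critic mode; the
        eta factor means only close BMU matches take large value steps.
        """
        if self.n_actions is None:
            self.values[unit] += self.rho * eta_prev * (target - self.values[unit])
        else:
            if action is None:
                raise ValueError("action index required in Q mode")
            self.values[unit, action] += self.rho * eta_prev * (
                target - self.values[unit, action])

    def replay_batch(self, batch_size: int, normalizer: RangeNormalizer,
                     rng: np.random.Generator) -> TrainingBatch:
        """Sample unit memories as a training batch for the network.

        States are unit weights mapped back through the normalizer inverse
        into agent input space; actions are uniform random; targets are the
        stored Q values. Sampling is with replacement.
        """
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_actions is None:
            raise ValueError("replay is defined for Q mode only")
        units = rng.integers(self.n_units, size=batch_size)
        actions = rng.integers(self.n_actions, size=batch_size)
        states = normalizer.denormalize(self.unit_weights[units])
        targets = self.values[units, actions]
        return TrainingBatch(states, targets, actions)

    # -- persistence -------------------------------------------------------

    def snapshot(self, normalizer: RangeNormalizer | None = None) -> dict:
        snap = {
            "side": self.side,
            "unit_weights": self.unit_weights.tolist(),
            "values": self.values.tolist(),
        }
        if normalizer is not None:
            snap["normalizer"] = normalizer.state_dict()
        return snap

    def to_json(self, normalizer: RangeNormalizer | None = None) -> str:
        return json.dumps(self.snapshot(normalizer))
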