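"""Exploration schedule and epsilon-greedy action selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EpsilonSchedule", "select_action_egreedy"]


@dataclass(frozen=True)
class EpsilonSchedule:
    """Linear anneal from ``start`` to ``floor`` over ``anneal_episodes``."""

    start: float = 1.0
    floor: float = 0.1
    anneal_episodes: int = 200

    def __call__(self, episode: int) -> float:
        if episode < 0:
            raise ValueError("episode index must be >= 0")
        if episode >= self.anneal_episodes:
            return self.floor
        frac = episode / self.anneal_episodes
        return self.start + frac * (self.floor - self.start)


def select_action_egreedy(q: np.ndarray, epsilon: float,
                          rng: np.random.Generator) -> int:
    """Uniform random with probability epsilon, else argmax with uniform
    tie-breaking. Always consumes exactly two draws for reproducibility
    across agents sharing a policy stream."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("empty action-value vector")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    explore = rng.random() < epsilon
    if explore:
        return int(rng.integers(q.size))
    ties = np.flatnonzero(q == q.max())
    return int(ties[rng.integers(ties.size)])
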