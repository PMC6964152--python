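"""Shared environment contract: transitions, specs, and the step/reset API."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Transition", "EnvSpec", "Environment"]


@dataclass(frozen=True)
class Transition:
    """One environment step: (s_t, a_t, r_{t+1}, s_{t+1}) plus end flags.

    ``terminal`` marks a task-defined end (goal reached, pole fallen);
    ``truncated`` marks the step cap. Bootstrapped targets treat only
    ``terminal`` as the absorbing case — a truncated episode still
    bootstraps from ``next_state``.
    """

    state: np.ndarray
    action: object
    reward: float
    next_state: np.ndarray
    terminal: bool = False
    truncated: bool = False

    def __post_init__(self):
        if not np.isfinite(self.reward):
            raise ValueError("transition reward must be finite")


@dataclass(frozen=True)
class EnvSpec:
    """Static description of an environment's interface.

    ``action_space`` is an integer (number of discrete actions) or a
    ``(low, high)`` tuple for a continuous scalar action.
    """

    state_dim: int
    state_bounds: tuple = ()
    action_space: object = 2
    max_steps: int = 1000

    def __post_init__(self):
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if isinstance(self.action_space, int):
            if self.action_space < 2:
                raise ValueError("discrete action space needs >= 2 actions")
        else:
            low, high = self.action_space
            if not high > low:
                raise ValueError("continuous action interval is degenerate")

    @property
    def discrete(self) -> bool:
        return isinstance(self.action_space, int)

    @property
    def n_actions(self) -> int:
        if not self.discrete:
            raise ValueError("continuous action space has no action count")
        return self.action_space


class Environment:
    """Minimal step/reset interface all three tasks implement.

    Subclasses hold the per-episode step counter and flag ``truncated``
    on the transition that hits ``spec.max_steps``.
    """

    spec: EnvSpec

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def step(self, action) -> Transition:
        raise NotImplementedError

    def goal_reached(self, t: Transition) -> bool:
        """Whether ``t`` ended the episode by solving the task (as opposed
        to failing or timing out). False for tasks without a goal state."""
        return False
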