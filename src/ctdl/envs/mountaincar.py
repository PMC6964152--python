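"""Continuous-action mountain car.

State (position, velocity); the agent applies a force in [-1, 1]. The
engine is too weak to climb the right hill directly, so momentum must be
built by rocking. Each step costs the squared force; reaching the target
position adds +100 and ends the episode; otherwise the episode truncates
at 1000 steps.
"""

from __future__ import annotations

import numpy as np

from .base import Environment, EnvSpec, Transition

__all__ = ["MountainCarEnv", "mountaincar_step"]

POS_MIN, POS_MAX = -1.2, 0.6
VEL_MAX = 0.07
FORCE_COEF = 0.0015
GRAVITY_COEF = 0.0025
TARGET_POS = 0.45
GOAL_REWARD = 100.0
MAX_STEPS = 1000
ACTION_PENALTY = 1.0  # coefficient on force^2


def mountaincar_step(state: np.ndarray, force: float,
                     action_penalty: float = ACTION_PENALTY) -> Transition:
    """One step of the mountain-car dynamics; reward -penalty*force^2,
    plus +100 on the step that reaches the target position."""
    state = np.asarray(state, dtype=float)
    pos, vel = state
    if not (-1.0 <= force <= 1.0):
        raise ValueError(f"force {force} outside [-1, 1]")
    if not (POS_MIN <= pos <= POS_MAX and -VEL_MAX <= vel <= VEL_MAX):
        raise ValueError(f"state {state} outside the task bounds")
    vel = np.clip(vel + force * FORCE_COEF - GRAVITY_COEF * np.cos(3 * pos),
                  -VEL_MAX, VEL_MAX)
    pos = np.clip(pos + vel, POS_MIN, POS_MAX)
    terminal = bool(pos >= TARGET_POS)
    reward = -action_penalty * force**2 + (GOAL_REWARD if terminal else 0.0)
    return Transition(state, float(force), float(reward),
                      np.array([pos, vel]), terminal=terminal)


class MountainCarEnv(Environment):
    def __init__(self, max_steps: int = MAX_STEPS,
                 action_penalty: float = ACTION_PENALTY):
        self.spec = EnvSpec(
            state_dim=2,
            state_bounds=((POS_MIN, POS_MAX), (-VEL_MAX, VEL_MAX)),
            action_space=(-1.0, 1.0),
            max_steps=max_steps,
        )
        self.action_penalty = action_penalty
        self._state = np.zeros(2)
        self._steps = 0

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        self._state = np.array([rng.uniform(-0.6, -0.4), 0.0])
        self._steps = 0
        return self._state.copy()

    def step(self, force: float) -> Transition:
        t = mountaincar_step(self._state, float(force), self.action_penalty)
        self._steps += 1
        self._state = t.next_state
        if not t.terminal and self._steps >= self.spec.max_steps:
            t = Transition(t.state, t.action, t.reward, t.next_state,
                           terminal=False, truncated=True)
        return t

    def goal_reached(self, t: Transition) -> bool:
        return t.terminal
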