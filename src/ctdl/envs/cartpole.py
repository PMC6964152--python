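"""Cart-pole balancing with classic-control dynamics.

State (x, x_dot, theta, theta_dot); two actions push the cart left or
right with a fixed force. Euler integration at dt = 0.02 with the usual
constants (gravity 9.8, cart mass 1.0, pole mass 0.1, half-length 0.5,
force 10 N). Reward is +1 every step; the episode fails when the pole
tilts past 15 degrees or the cart leaves the +-2.4 track, and truncates
at 500 steps.
"""

from __future__ import annotations

import numpy as np

from .base import Environment, EnvSpec, Transition

__all__ = ["CartPoleEnv", "cartpole_step"]

GRAVITY = 9.8
CART_MASS = 1.0
POLE_MASS = 0.1
TOTAL_MASS = CART_MASS + POLE_MASS
HALF_LENGTH = 0.5
POLE_MASS_LENGTH = POLE_MASS * HALF_LENGTH
FORCE_MAG = 10.0
DT = 0.02
ANGLE_LIMIT = np.deg2rad(15.0)
X_LIMIT = 2.4
MAX_STEPS = 500


def cartpole_step(state: np.ndarray, action: int) -> Transition:
    """One Euler step of the cart-pole dynamics; +1 reward every step."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite cart-pole state")
    if action not in (0, 1):
        raise ValueError(f"unknown action {action!r}; 0=left, 1=right")
    x, x_dot, theta, theta_dot = state
    force = FORCE_MAG if action == 1 else -FORCE_MAG
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    temp = (force + POLE_MASS_LENGTH * theta_dot**2 * sin_t) / TOTAL_MASS
    theta_acc = (GRAVITY * sin_t - cos_t * temp) / (
        HALF_LENGTH * (4.0 / 3.0 - POLE_MASS * cos_t**2 / TOTAL_MASS))
    x_acc = temp - POLE_MASS_LENGTH * theta_acc * cos_t / TOTAL_MASS
    nxt = np.array([
        x + DT * x_dot,
        x_dot + DT * x_acc,
        theta + DT * theta_dot,
        theta_dot + DT * theta_acc,
    ])
    terminal = bool(abs(nxt[2]) > ANGLE_LIMIT or abs(nxt[0]) > X_LIMIT)
    return Transition(state, action, 1.0, nxt, terminal=terminal)


class CartPoleEnv(Environment):
    def __init__(self, max_steps: int = MAX_STEPS):
        self.spec = EnvSpec(
            state_dim=4,
            state_bounds=((-4.8, 4.8), (-np.inf, np.inf),
                          (-ANGLE_LIMIT, ANGLE_LIMIT), (-np.inf, np.inf)),
            action_space=2,
            max_steps=max_steps,
        )
        self._state = np.zeros(4)
        self._steps = 0

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        self._state = rng.uniform(-0.05, 0.05, size=4)
        self._steps = 0
        return self._state.copy()

    def step(self, action: int) -> Transition:
        t = cartpole_step(self._state, int(action))
        self._steps += 1
        self._state = t.next_state
        if not t.terminal and self._steps >= self.spec.max_steps:
            t = Transition(t.state, t.action, t.reward, t.next_state,
                           terminal=False, truncated=True)
        return t
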