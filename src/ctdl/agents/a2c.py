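"""Advantage actor-critic for continuous actions, and its SOM-fused variant.

The actor network outputs a Gaussian policy's mean and a raw spread
parameter (softplus-transformed and clamped); the critic outputs a scalar
state value. Both are trained online with Adam from one-step advantages —
no replay buffer and no target network.

``CTDLA2CAgent`` adds the complementary memory: a SOM in scalar-value
mode whose V(u) records are fused with the critic by the same
distance-decayed weight eta used in the discrete-action agent, and whose
plasticity is gated by the critic's TD error.
"""

from __future__ import annotations

import numpy as np

from ..envs.base import EnvSpec, Transition
from ..nn import MLP, Adam, TrainingBatch
from ..seeding import RngStreams
from ..som import RangeNormalizer, SOMMemory

__all__ = ["A2CAgent", "CTDLA2CAgent", "gaussian_policy_sample"]

SPREAD_MIN, SPREAD_MAX = 1e-2, 1.0


def _spread(raw: float) -> tuple[float, float]:
    """Softplus then clamp; returns (spread, d spread / d raw)."""
    sp = float(np.logaddexp(0.0, raw))  # softplus
    grad = float(1.0 / (1.0 + np.exp(-raw)))
    if sp <= SPREAD_MIN:
        return SPREAD_MIN, 0.0
    if sp >= SPREAD_MAX:
        return SPREAD_MAX, 0.0
    return sp, grad


def gaussian_policy_sample(actor_output: np.ndarray, rng: np.random.Generator):
    """Sample a clipped action from the actor's Gaussian head.

    Returns (action in [-1, 1], log-density of the pre-clip sample,
    pre-clip sample). The log-density refers to the unclipped draw.
    """
    mean, raw = float(actor_output[0]), float(actor_output[1])
    spread, _ = _spread(raw)
    sample = mean + spread * rng.standard_normal()
    logp = -0.5 * ((sample - mean) / spread) ** 2 - np.log(spread) \
        - 0.5 * np.log(2 * np.pi)
    return float(np.clip(sample, -1.0, 1.0)), float(logp), float(sample)


class A2CAgent:
    def __init__(
        self,
        env_spec: EnvSpec,
        seed: int,
        hidden: tuple[int, ...] = (128, 128),
        gamma: float = 0.99,
        critic_lr: float = 0.0001,
        actor_lr: float = 0.00001,
    ):
        if env_spec.discrete:
            raise ValueError("A2C here drives a continuous scalar action")
        self.spec = env_spec
        self.gamma = gamma
        streams = RngStreams(seed)
        self._policy_rng = streams["policy"]
        self.actor = MLP([env_spec.state_dim, *hidden, 2], streams["actor_init"],
                         output_scale=0.0)
        self.critic = MLP([env_spec.state_dim, *hidden, 1], streams["critic_init"],
                          output_scale=0.0)
        self.actor_opt = Adam(self.actor, lr=actor_lr)
        self.critic_opt = Adam(self.critic, lr=critic_lr)
        self.total_steps = 0
        self.episode = -1
        self._cache: dict | None = None
        self.last_td = 0.0

    def begin_episode(self, state: np.ndarray) -> None:
        self.episode += 1
        self._cache = None

    def act(self, state: np.ndarray) -> float:
        out = self.actor.forward(state)
        action, logp, sample = gaussian_policy_sample(out, self._policy_rng)
        self._cache = {"sample": sample}
        return action

    # -- learning ----------------------------------------------------------

    def _value(self, state: np.ndarray) -> float:
        return float(self.critic.forward(state)[0])

    def _critic_target(self, t: Transition) -> float:
        if t.terminal:
            return float(t.reward)
        return float(t.reward + self.gamma * self._value(t.next_state))

    def _actor_step(self, t: Transition, advantage: float) -> None:
        """Score-function step on -log pi(a|s) * advantage."""
        out = self.actor.forward(t.state)
        mean, raw = float(out[0]), float(out[1])
        spread, dspread = _spread(raw)
        cache = self._cache
        sample = cache["sample"] if cache is not None else float(t.action)
        z = (sample - mean) / spread
        dlogp_dmean = z / spread
        dlogp_dspread = (z * z - 1.0) / spread
        dout = np.array([[-advantage * dlogp_dmean,
                          -advantage * dlogp_dspread * dspread]])
        gw, gb = self.actor.backward(t.state[None, :], dout)
        self.actor_opt.step(self.actor, gw, gb)

    def _critic_step(self, t: Transition, y: float) -> None:
        batch = TrainingBatch(t.state[None, :], [y], [0])
        self.critic_opt.step(self.critic, *self.critic.gradients(batch))

    def observe(self, t: Transition) -> dict:
        y = self._critic_target(t)
        advantage = y - self._value(t.state)
        if not np.isfinite(advantage):
            raise FloatingPointError("non-finite advantage: training diverged")
        self._critic_step(t, y)
        self._actor_step(t, advantage)
        self.total_steps += 1
        self._cache = None
        self.last_td = advantage
        return {"y": y, "advantage": advantage}

    def snapshot(self) -> dict:
        return {"total_steps": self.total_steps}


class CTDLA2CAgent(A2CAgent):
    """A2C whose critic is fused with a scalar-value SOM memory."""

    def __init__(
        self,
        env_spec: EnvSpec,
        seed: int,
        hidden: tuple[int, ...] = (128, 128),
        gamma: float = 0.99,
        critic_lr: float = 0.0001,
        actor_lr: float = 0.00001,
        som_units: int = 36,
        tau_eta: float = 10.0,
        tau_delta: float = 1.0,
        sigma: float = 0.1,
        sigma_const: float = 0.1,
        alpha: float = 0.01,
        rho: float = 0.9,
        eta_override: float | None = None,
    ):
        super().__init__(env_spec, seed, hidden, gamma, critic_lr, actor_lr)
        streams = RngStreams(seed)
        self.som = SOMMemory(
            som_units, env_spec.state_dim, None, streams["som_init"],
            tau_eta=tau_eta, tau_delta=tau_delta, sigma=sigma,
            sigma_const=sigma_const, alpha=alpha, rho=rho,
        )
        self.normalizer = RangeNormalizer(env_spec.state_dim)
        self.eta_override = eta_override
        self._som_cache: dict | None = None
        self.last_eta = 0.0

    def _eta(self, distance: float) -> float:
        if self.eta_override is not None:
            return self.eta_override
        return self.som.eta(distance)

    def fused_value(self, state: np.ndarray):
        """eta * V_SOM(bmu) + (1 - eta) * V_critic(s)."""
        s_norm = self.normalizer.normalize(state, update=False)
        bmu, dist = self.som.best_matching_unit(s_norm)
        eta = self._eta(dist)
        v = eta * float(self.som.values[bmu]) + (1.0 - eta) * self._value(state)
        return v, eta, bmu, s_norm

    def act(self, state: np.ndarray) -> float:
        self.normalizer.observe(state)
        v, eta, bmu, s_norm = self.fused_value(state)
        self._som_cache = {"s_norm": s_norm, "bmu": bmu, "eta": eta}
        self.last_eta = eta
        return super().act(state)

    def _critic_target(self, t: Transition) -> float:
        if t.terminal:
            return float(t.reward)
        v_next, *_ = self.fused_value(t.next_state)
        return float(t.reward + self.gamma * v_next)

    def observe(self, t: Transition) -> dict:
        y = self._critic_target(t)
        td = y - self._value(t.state)
        if not np.isfinite(td):
            raise FloatingPointError("non-finite TD error: training diverged")
        self._critic_step(t, y)
        self._actor_step(t, td)

        delta = self.som.delta(td)
        cache = self._som_cache
        if cache is None:
            s_norm = self.normalizer.normalize(t.state)
            bmu, dist = self.som.best_matching_unit(s_norm)
            eta = self._eta(dist)
        else:
            s_norm, bmu, eta = cache["s_norm"], cache["bmu"], cache["eta"]
        self.som.weight_update(s_norm, bmu, delta)
        self.som.value_update(bmu, None, y, eta)

        self.total_steps += 1
        self._cache = None
        self._som_cache = None
        self.last_td, self.last_delta = td, delta
        return {"y": y, "advantage": td, "delta": delta, "eta": eta}

    def snapshot(self) -> dict:
        return self.som.snapshot(self.normalizer)
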