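"""The CTDL agent: a Q-network fused with a TD-gated SOM memory.

At each state the agent retrieves the best-matching SOM unit, computes the
fusion weight eta from the retrieval distance, and acts epsilon-greedily on

    q(s, .) = eta * Q_SOM(bmu, .) + (1 - eta) * Q_DNN(s, .).

Learning per transition: the bootstrapped target y uses the fused value of
the next state (network half read from the periodically synchronized
target copy); the online network takes one gradient step toward y on the
taken action; the TD error y - Q_DNN(s, a) sets the plasticity gain delta
that drives the SOM weight update toward the current state; the BMU cached
at action selection has its stored value moved toward y with step
rho * eta; finally one batch of SOM memories is replayed to the network.
No transition buffer is kept.
"""

from __future__ import annotations

import numpy as np

from ..envs.base import EnvSpec, Transition
from ..nn import MLP, RMSProp, TrainingBatch, sync_target
from ..seeding import RngStreams
from ..som import RangeNormalizer, SOMMemory
from .schedules import EpsilonSchedule, select_action_egreedy

__all__ = ["CTDLAgent"]


class CTDLAgent:
    def __init__(
        self,
        env_spec: EnvSpec,
        seed: int,
        hidden: tuple[int, ...] = (128, 128),
        som_units: int = 36,
        gamma: float = 0.99,
        target_sync: int = 10_000,
        lr: float = 0.00025,
        kappa: float = 0.95,
        denom_const: float = 0.01,
        batch_size: int = 32,
        tau_eta: float = 10.0,
        tau_delta: float = 1.0,
        sigma: float = 0.1,
        sigma_const: float = 0.1,
        alpha: float = 0.01,
        rho: float = 0.9,
        epsilon_schedule: EpsilonSchedule | None = None,
        replay_enabled: bool = True,
        som_learning_enabled: bool = True,
        eta_override: float | None = None,
        target_mode: str = "fused",
    ):
        if not 0.0 < gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if target_mode not in ("fused", "dnn"):
            raise ValueError("target_mode must be 'fused' or 'dnn'")
        self.spec = env_spec
        self.gamma = gamma
        self.target_sync = target_sync
        self.batch_size = batch_size
        self.epsilon_schedule = epsilon_schedule or EpsilonSchedule()
        self.replay_enabled = replay_enabled
        self.som_learning_enabled = som_learning_enabled
        self.eta_override = eta_override
        self.target_mode = target_mode

        streams = RngStreams(seed)
        self._policy_rng = streams["policy"]
        self._replay_rng = streams["replay"]
        sizes = [env_spec.state_dim, *hidden, env_spec.n_actions]
        self.online = MLP(sizes, streams["net_init"], output_scale=0.0)
        self.target = sync_target(self.online)
        self.optimizer = RMSProp(self.online, lr=lr, kappa=kappa,
                                 denom_const=denom_const)
        self.som = SOMMemory(
            som_units, env_spec.state_dim, env_spec.n_actions,
            streams["som_init"], tau_eta=tau_eta, tau_delta=tau_delta,
            sigma=sigma, sigma_const=sigma_const,
            alpha=0.0 if not som_learning_enabled else alpha, rho=rho,
        )
        self.normalizer = RangeNormalizer(env_spec.state_dim)

        self.total_steps = 0
        self.episode = -1
        self._cache: dict | None = None
        self.last_eta = 0.0
        self.last_td = 0.0
        self.last_delta = 0.0

    # -- policy ------------------------------------------------------------

    @property
    def epsilon(self) -> float:
        return self.epsilon_schedule(max(self.episode, 0))

    def _eta(self, distance: float) -> float:
        if self.eta_override is not None:
            return self.eta_override
        return self.som.eta(distance)

    def fused_q(self, state: np.ndarray, network: MLP | None = None):
        """Fused action values; returns (q, eta, bmu, distance, s_norm)."""
        net = self.online if network is None else network
        s_norm = self.normalizer.normalize(state, update=False)
        bmu, dist = self.som.best_matching_unit(s_norm)
        eta = self._eta(dist)
        q = eta * self.som.values[bmu] + (1.0 - eta) * net.forward(state)
        return q, eta, bmu, dist, s_norm

    def begin_episode(self, state: np.ndarray) -> None:
        self.episode += 1
        self._cache = None

    def act(self, state: np.ndarray) -> int:
        self.normalizer.observe(state)
        q, eta, bmu, dist, s_norm = self.fused_q(state)
        action = select_action_egreedy(q, self.epsilon, self._policy_rng)
        self._cache = {"s_norm": s_norm, "bmu": bmu, "eta": eta, "action": action}
        self.last_eta = eta
        return action

    # -- learning ----------------------------------------------------------

    def _target_value(self, t: Transition) -> float:
        if t.terminal:
            return float(t.reward)
        if self.target_mode == "fused":
            qn, *_ = self.fused_q(t.next_state, network=self.target)
        else:
            qn = self.target.forward(t.next_state)
        return float(t.reward + self.gamma * np.max(qn))

    def observe(self, t: Transition) -> dict:
        y = self._target_value(t)
        action = int(t.action)
        td = y - float(self.online.forward(t.state)[action])
        if not np.isfinite(td):
            raise FloatingPointError("non-finite TD error: training diverged")

        batch = TrainingBatch(t.state[None, :], [y], [action])
        self.optimizer.step(self.online, *self.online.gradients(batch))

        delta = self.som.delta(td)
        cache = self._cache
        if cache is None or cache["action"] != action:
            # transition not produced by this agent's last act(); recompute
            s_norm = self.normalizer.normalize(t.state)
            bmu, dist = self.som.best_matching_unit(s_norm)
            eta = self._eta(dist)
        else:
            s_norm, bmu, eta = cache["s_norm"], cache["bmu"], cache["eta"]
        if self.som_learning_enabled:
            self.som.weight_update(s_norm, bmu, delta)
        self.som.value_update(bmu, action, y, eta)

        if self.replay_enabled:
            replay = self.som.replay_batch(self.batch_size, self.normalizer,
                                           self._replay_rng)
            self.optimizer.step(self.online, *self.online.gradients(replay))

        self.total_steps += 1
        if self.total_steps % self.target_sync == 0:
            self.target = sync_target(self.online)
        self._cache = None
        self.last_td, self.last_delta = td, delta
        return {"y": y, "td_error": td, "delta": delta, "eta": eta}

    # -- persistence -------------------------------------------------------

    def snapshot(self) -> dict:
        return self.som.snapshot(self.normalizer)
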