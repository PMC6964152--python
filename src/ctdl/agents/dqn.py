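"""Deep Q-network baseline with experience replay and a target network.

The standard comparison agent: epsilon-greedy over the online network's
action values, uniform minibatch replay from a bounded FIFO buffer, and a
target copy refreshed every ``target_sync`` steps. ``use_buffer=False``
gives the buffer-less variant that trains on each transition as it
arrives (the network half of CTDL in isolation).
"""

from __future__ import annotations

import numpy as np

from ..envs.base import EnvSpec, Transition
from ..nn import MLP, RMSProp, TrainingBatch, sync_target
from ..seeding import RngStreams
from .replay import ReplayBuffer
from .schedules import EpsilonSchedule, select_action_egreedy

__all__ = ["DQNAgent"]


class DQNAgent:
    def __init__(
        self,
        env_spec: EnvSpec,
        seed: int,
        hidden: tuple[int, ...] = (128, 128),
        gamma: float = 0.99,
        target_sync: int = 10_000,
        lr: float = 0.00025,
        kappa: float = 0.95,
        denom_const: float = 0.01,
        batch_size: int = 32,
        buffer_size: int = 100_000,
        use_buffer: bool = True,
        epsilon_schedule: EpsilonSchedule | None = None,
    ):
        if not 0.0 < gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        self.spec = env_spec
        self.gamma = gamma
        self.target_sync = target_sync
        self.batch_size = batch_size
        self.use_buffer = use_buffer
        self.epsilon_schedule = epsilon_schedule or EpsilonSchedule()

        streams = RngStreams(seed)
        self._policy_rng = streams["policy"]
        self._sample_rng = streams["replay"]
        sizes = [env_spec.state_dim, *hidden, env_spec.n_actions]
        self.online = MLP(sizes, streams["net_init"], output_scale=0.0)
        self.target = sync_target(self.online)
        self.optimizer = RMSProp(self.online, lr=lr, kappa=kappa,
                                 denom_const=denom_const)
        self.buffer = ReplayBuffer(buffer_size) if use_buffer else None

        self.total_steps = 0
        self.episode = -1
        self.skipped_updates = 0
        self.last_td = 0.0

    @property
    def epsilon(self) -> float:
        return self.epsilon_schedule(max(self.episode, 0))

    def begin_episode(self, state: np.ndarray) -> None:
        self.episode += 1

    def act(self, state: np.ndarray) -> int:
        q = self.online.forward(state)
        return select_action_egreedy(q, self.epsilon, self._policy_rng)

    def _train_on(self, transitions: list[Transition]) -> None:
        states = np.stack([t.state for t in transitions])
        next_states = np.stack([t.next_state for t in transitions])
        rewards = np.array([t.reward for t in transitions])
        terminal = np.array([t.terminal for t in transitions])
        actions = np.array([int(t.action) for t in transitions])
        q_next = np.atleast_2d(self.target.forward(next_states)).max(axis=1)
        targets = rewards + self.gamma * q_next * (~terminal)
        batch = TrainingBatch(states, targets, actions)
        pred = np.atleast_2d(self.online.forward(states))[np.arange(len(actions)), actions]
        self.last_td = float(np.mean(targets - pred))
        self.optimizer.step(self.online, *self.online.gradients(batch))

    def observe(self, t: Transition) -> dict:
        if self.use_buffer:
            self.buffer.append(t)
            if len(self.buffer) >= self.batch_size:
                self._train_on(self.buffer.sample(self.batch_size, self._sample_rng))
            else:
                self.skipped_updates += 1  # buffer not yet one batch deep
        else:
            self._train_on([t])
        self.total_steps += 1
        if self.total_steps % self.target_sync == 0:
            self.target = sync_target(self.online)
        return {"td_error": self.last_td}

    def snapshot(self) -> dict:
        return {"total_steps": self.total_steps}
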