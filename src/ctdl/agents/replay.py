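"""Bounded FIFO experience replay buffer for the DQN baseline."""

from __future__ import annotations

from collections import deque

import numpy as np

from ..envs.base import Transition

__all__ = ["ReplayBuffer"]


class ReplayBuffer:
    """FIFO store of transitions; the oldest entry is evicted at capacity."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._buf: deque[Transition] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._buf)

    def append(self, t: Transition) -> None:
        self._buf.append(t)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        """Uniform sample with replacement."""
        if len(self._buf) == 0:
            raise ValueError("cannot sample from an empty buffer")
        idx = rng.integers(len(self._buf), size=batch_size)
        return [self._buf[int(i)] for i in idx]

    def oldest(self) -> Transition:
        return self._buf[0]
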