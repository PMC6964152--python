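"""Named random streams fanned out from one root seed.

Every source of randomness in an experiment (environment resets, network
initialization, the behaviour policy, SOM initialization and replay
sampling) draws from its own named stream so that ablations which remove
one consumer leave the others' draws untouched.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_seed", "stream_rng", "RngStreams"]


def stream_seed(root_seed: int, name: str) -> int:
    """Derive a deterministic child seed (< 2**31) for a named stream."""
    tag = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence([root_seed, tag]).generate_state(1)[0] % (2**31))


def stream_rng(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(stream_seed(root_seed, name))


class RngStreams:
    """Lazy dictionary of named generators derived from one root seed."""

    def __init__(self, root_seed: int):
        self.root_seed = int(root_seed)
        self._streams: dict[str, np.random.Generator] = {}

    def __getitem__(self, name: str) -> np.random.Generator:
        if name not in self._streams:
            self._streams[name] = stream_rng(self.root_seed, name)
        return self._streams[name]
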