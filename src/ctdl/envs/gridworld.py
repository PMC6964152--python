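"""Procedurally generated 2D grid worlds.

Each cell is a state (x, y) with 0-based integer coordinates, y increasing
upward. A world carries one goal cell (+1, absorbing), one start cell, and
floor(W*H/5) negative-reward cells (-1 on each entry, non-terminal by
default). Symmetric worlds have a negative-cell set invariant under the
horizontal mirror x -> W-1-x, with start and goal on the midline column(s).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass

import numpy as np

from .base import Environment, EnvSpec, Transition

__all__ = [
    "GridWorld",
    "GridWorldEnv",
    "generate_grid_world",
    "ACTIONS",
    "upwards_maze",
    "one_obstacle_maze",
    "two_obstacle_maze",
]

# action index -> (dx, dy); y increases upward
ACTIONS: dict[int, tuple[int, int]] = {0: (0, 1), 1: (0, -1), 2: (-1, 0), 3: (1, 0)}
ACTION_NAMES = ("up", "down", "left", "right")


@dataclass(frozen=True)
class GridWorld:
    width: int
    height: int
    negative_cells: frozenset
    goal_cell: tuple[int, int]
    start_cell: tuple[int, int]
    symmetric: bool = False

    def __post_init__(self):
        cells = set(self.negative_cells) | {self.goal_cell, self.start_cell}
        for x, y in cells:
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"cell {(x, y)} outside {self.width}x{self.height} grid")
        if self.goal_cell == self.start_cell:
            raise ValueError("goal and start coincide")
        if self.goal_cell in self.negative_cells or self.start_cell in self.negative_cells:
            raise ValueError("goal/start overlap a negative cell")
        if self.symmetric:
            mirror = {(self.width - 1 - x, y) for x, y in self.negative_cells}
            if mirror != set(self.negative_cells):
                raise ValueError("negative cells are not mirror symmetric")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        x, y = cell
        return 0 <= x < self.width and 0 <= y < self.height

    def to_json(self) -> str:
        return json.dumps(
            {
                "width": self.width,
                "height": self.height,
                "negative_cells": sorted(map(list, self.negative_cells)),
                "goal_cell": list(self.goal_cell),
                "start_cell": list(self.start_cell),
                "symmetric": self.symmetric,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GridWorld":
        d = json.loads(text)
        return cls(
            width=d["width"],
            height=d["height"],
            negative_cells=frozenset(tuple(c) for c in d["negative_cells"]),
            goal_cell=tuple(d["goal_cell"]),
            start_cell=tuple(d["start_cell"]),
            symmetric=d.get("symmetric", False),
        )

    def render(self) -> str:
        """ASCII rendering, top row = highest y. G goal, S start, - negative."""
        rows = []
        for y in reversed(range(self.height)):
            row = []
            for x in range(self.width):
                c = (x, y)
                if c == self.goal_cell:
                    row.append("G")
                elif c == self.start_cell:
                    row.append("S")
                elif c in self.negative_cells:
                    row.append("-")
                else:
                    row.append(".")
            rows.append("".join(row))
        return "\n".join(rows)


def _reachable(world: GridWorld) -> bool:
    """Breadth-first search from start to goal through non-negative cells."""
    seen = {world.start_cell}
    queue = deque([world.start_cell])
    while queue:
        x, y = queue.popleft()
        if (x, y) == world.goal_cell:
            return True
        for dx, dy in ACTIONS.values():
            nxt = (x + dx, y + dy)
            if world.in_bounds(nxt) and nxt not in seen and nxt not in world.negative_cells:
                seen.add(nxt)
                queue.append(nxt)
    return False


def generate_grid_world(
    width: int,
    height: int,
    symmetric: bool = True,
    rng: np.random.Generator | None = None,
    max_tries: int = 1000,
) -> GridWorld:
    """Sample a solvable grid world with floor(W*H/5) negative cells.

    Symmetric worlds sample negatives as mirror pairs (plus midline
    singletons when the width is odd) and place start and goal on the
    midline column(s). Worlds whose goal is unreachable from the start
    through non-negative cells are rejected and resampled.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    n_cells = width * height
    if n_cells < 10:
        raise ValueError("grid too small: need width*height >= 10")
    n_neg = n_cells // 5
    if n_cells - n_neg < 2:
        raise ValueError("no room for disjoint start and goal")
    if symmetric and width % 2 == 0 and n_neg % 2 == 1:
        raise ValueError(
            "even width cannot host an odd symmetric negative-cell count"
        )

    mid_cols = [width // 2] if width % 2 == 1 else [width // 2 - 1, width // 2]

    for _ in range(max_tries):
        if symmetric:
            negatives = _sample_symmetric_negatives(width, height, n_neg, rng)
            free_mid = [
                (x, y) for x in mid_cols for y in range(height) if (x, y) not in negatives
            ]
            if len(free_mid) < 2:
                continue
            idx = rng.choice(len(free_mid), size=2, replace=False)
            start, goal = free_mid[idx[0]], free_mid[idx[1]]
        else:
            flat = rng.choice(n_cells, size=n_neg + 2, replace=False)
            cells = [(int(i) % width, int(i) // width) for i in flat]
            start, goal = cells[0], cells[1]
            negatives = frozenset(cells[2:])
        world = GridWorld(width, height, frozenset(negatives), goal, start, symmetric)
        if _reachable(world):
            return world
    raise RuntimeError(f"no solvable layout found in {max_tries} attempts")


def _sample_symmetric_negatives(width, height, n_neg, rng) -> frozenset:
    left = [(x, y) for x in range(width // 2) for y in range(height)]
    mid = [(width // 2, y) for y in range(height)] if width % 2 == 1 else []
    n_single = n_neg % 2
    n_pairs = n_neg // 2
    # odd width: pairs may come from the left half only; a midline cell is its
    # own mirror and covers the odd remainder
    negatives: set = set()
    pair_idx = rng.choice(len(left), size=min(n_pairs, len(left)), replace=False)
    for i in pair_idx:
        x, y = left[int(i)]
        negatives.add((x, y))
        negatives.add((width - 1 - x, y))
    if n_single:
        negatives.add(mid[int(rng.integers(len(mid)))])
    return frozenset(negatives)


class GridWorldEnv(Environment):
    """Deterministic four-action navigation over a :class:`GridWorld`.

    Moves are one cell with probability 1; a move off the grid leaves the
    agent in place for that step. Reward is +1 (terminal) on the goal,
    -1 on entering a negative cell, else 0. By default negative cells do
    not end the episode (``terminate_on_negative`` flips this).
    """

    def __init__(self, world: GridWorld, max_steps: int = 1000,
                 terminate_on_negative: bool = False):
        self.world = world
        self.terminate_on_negative = terminate_on_negative
        self.spec = EnvSpec(
            state_dim=2,
            state_bounds=((0, world.width - 1), (0, world.height - 1)),
            action_space=4,
            max_steps=max_steps,
        )
        self._pos = world.start_cell
        self._steps = 0

    def reset(self, rng: np.random.Generator | None = None) -> np.ndarray:
        self._pos = self.world.start_cell
        self._steps = 0
        return np.asarray(self._pos, dtype=float)

    def step(self, action: int) -> Transition:
        t = grid_step(self.world, self._pos, int(action),
                      terminate_on_negative=self.terminate_on_negative)
        self._steps += 1
        self._pos = (int(t.next_state[0]), int(t.next_state[1]))
        if not t.terminal and self._steps >= self.spec.max_steps:
            t = Transition(t.state, t.action, t.reward, t.next_state,
                           terminal=False, truncated=True)
        return t

    def goal_reached(self, t: Transition) -> bool:
        return t.terminal and t.reward > 0


def grid_step(world: GridWorld, pos: tuple[int, int], action: int,
              terminate_on_negative: bool = False) -> Transition:
    """One deterministic move; see :class:`GridWorldEnv` for the reward rule."""
    if not world.in_bounds(pos):
        raise ValueError(f"position {pos} out of bounds")
    if pos == world.goal_cell:
        raise ValueError("cannot step from the absorbing goal cell")
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}; expected 0..3 "
                         f"({'/'.join(ACTION_NAMES)})")
    dx, dy = ACTIONS[action]
    nxt = (pos[0] + dx, pos[1] + dy)
    if not world.in_bounds(nxt):
        nxt = pos  # blocked move: remain in place for this time step
    if nxt == world.goal_cell:
        reward, terminal = 1.0, True
    elif nxt in world.negative_cells:
        reward, terminal = -1.0, bool(terminate_on_negative)
    else:
        reward, terminal = 0.0, False
    return Transition(
        state=np.asarray(pos, dtype=float),
        action=action,
        reward=reward,
        next_state=np.asarray(nxt, dtype=float),
        terminal=terminal,
    )


# ---------------------------------------------------------------------------
# Reconstructed benchmark layouts (10x10, mirror-symmetric). The published
# figures give these mazes only graphically; the layouts below reconstruct
# their described topology - a 'move upwards' rule maze with no hazards
# between start and goal, then the same maze with one and with two obstacle
# walls that violate the rule - not the exact cell lists. Unlike generated
# worlds they carry only the hazards the topology calls for.
# ---------------------------------------------------------------------------

_EDGE_CELLS = {(0, 2), (9, 2), (0, 7), (9, 7)}  # edge hazards off any path


def upwards_maze() -> GridWorld:
    """Rule maze: travelling straight upwards reaches the goal.

    The few negative cells sit on the outer columns, so 'increase y' is a
    valid generalization from anywhere between them.
    """
    return GridWorld(10, 10, frozenset(_EDGE_CELLS), (4, 9), (4, 0),
                     symmetric=True)


def one_obstacle_maze() -> GridWorld:
    """The upwards maze with one wall across the corridor; the agent must
    circumnavigate through the edge gaps."""
    cells = set(_EDGE_CELLS) | {(x, 5) for x in range(2, 8)}
    return GridWorld(10, 10, frozenset(cells), (4, 9), (4, 0), symmetric=True)


def two_obstacle_maze() -> GridWorld:
    """The upwards maze with two staggered walls: an edge-gap wall below a
    centre-gap wall, forcing a zig-zag route."""
    cells = set(_EDGE_CELLS)
    cells |= {(x, 3) for x in range(2, 8)}                 # edge gaps
    cells |= {(x, 6) for x in (0, 1, 2, 3, 6, 7, 8, 9)}    # centre gap
    return GridWorld(10, 10, frozenset(cells), (4, 9), (4, 0), symmetric=True)
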