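"""Episode loops, learning-curve metrics, and the comparison protocols.

The full published protocol (50 mazes x 30 repeats x 1000 episodes, 100
cart-pole runs, 50 mountain-car runs) is reproducible through the config
layer; :data:`SCALED_GRID_PROFILE` records the package's scaled study
conditions for routine runs: episodes 1000 -> 150, step cap 1000 -> 200,
hidden widths 128 -> 32, 5 repeats, 16 SOM units as in the published
rule-violation mazes. The exploration anneal (200 -> 30 episodes) and the
target-sync interval (10000 -> 2000 steps) scale with the shorter runs,
mirroring the published practice of shrinking the sync interval for
shorter episodes; learning rates and buffer capacity keep their
published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envs.base import Environment, Transition
from .envs.gridworld import ACTIONS, GridWorld, GridWorldEnv, grid_step
from .seeding import stream_rng

__all__ = [
    "EpisodeResult",
    "RunRecord",
    "ComparisonSummary",
    "run_episode",
    "run_learning",
    "compare_agents",
    "sequential_maze_protocol",
    "value_iteration",
    "greedy_rollout",
    "som_location_map",
    "SCALED_GRID_PROFILE",
]

# scaled-down study conditions for grid-world comparisons (see module docs)
SCALED_GRID_PROFILE: dict = {
    "episodes": 150,
    "max_steps": 200,
    "hidden": (32, 32),
    "target_sync": 2000,
    "epsilon_anneal": 30,
    "som_units": 16,
    "buffer_size": 100_000,
    "repeats": 5,
}


def scaled_grid_factories(profile: dict | None = None,
                          agents: tuple = ("ctdl", "dqn")) -> dict:
    """Agent factories for grid-world comparisons at the scaled conditions.

    Returns {name: callable(env_spec, seed) -> agent} for use with
    :func:`compare_agents` and :func:`sequential_maze_protocol`.
    """
    from .agents.ctdl import CTDLAgent
    from .agents.dqn import DQNAgent
    from .agents.schedules import EpsilonSchedule

    p = dict(SCALED_GRID_PROFILE, **(profile or {}))
    schedule = EpsilonSchedule(anneal_episodes=p["epsilon_anneal"])

    def make_ctdl(spec, seed):
        return CTDLAgent(spec, seed, hidden=p["hidden"],
                         som_units=p["som_units"],
                         target_sync=p["target_sync"],
                         epsilon_schedule=schedule)

    def make_dqn(spec, seed):
        return DQNAgent(spec, seed, hidden=p["hidden"],
                        target_sync=p["target_sync"],
                        buffer_size=p["buffer_size"],
                        epsilon_schedule=schedule)

    table = {"ctdl": make_ctdl, "dqn": make_dqn}
    return {name: table[name] for name in agents}


@dataclass(frozen=True)
class EpisodeResult:
    total_reward: float
    steps: int
    reached_goal: bool
    ideal: bool
    epsilon: float = float("nan")
    mean_eta: float = float("nan")
    mean_abs_td: float = float("nan")

    def __post_init__(self):
        if self.ideal and not self.reached_goal:
            raise ValueError("an ideal episode must reach the goal")


@dataclass
class RunRecord:
    """Per-episode results with cumulative learning curves and snapshots."""

    results: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)  # (episode, dict)
    seed: int | None = None
    config: dict = field(default_factory=dict)
    switch_episode: int | None = None

    @property
    def episodes(self) -> int:
        return len(self.results)

    @property
    def cumulative_reward(self) -> np.ndarray:
        return np.cumsum([r.total_reward for r in self.results])

    @property
    def cumulative_ideal(self) -> np.ndarray:
        return np.cumsum([int(r.ideal) for r in self.results])

    @property
    def final_cumulative_reward(self) -> float:
        return float(self.cumulative_reward[-1]) if self.results else 0.0

    @property
    def final_cumulative_ideal(self) -> int:
        return int(self.cumulative_ideal[-1]) if self.results else 0


@dataclass
class ComparisonSummary:
    """Per-world end-of-learning means and per-agent win tallies."""

    agent_names: list
    world_means: dict          # metric -> array (n_worlds, n_agents)
    wins: dict                 # metric -> {agent: wins}; ties split 0.5/0.5

    def winner(self, metric: str = "cumulative_reward") -> str:
        tally = self.wins[metric]
        return max(tally, key=tally.get)


def run_episode(env: Environment, agent, rng: np.random.Generator,
                learn: bool = True) -> EpisodeResult:
    """One interaction episode, invoking the agent's learning step per
    transition. ``ideal`` is true iff the goal was reached with no
    negative reward incurred along the way."""
    state = env.reset(rng)
    agent.begin_episode(state)
    total = 0.0
    steps = 0
    negatives = 0
    reached = False
    etas, tds = [], []
    while True:
        action = agent.act(state)
        t = env.step(action)
        if learn:
            agent.observe(t)
        total += t.reward
        steps += 1
        if t.reward < 0:
            negatives += 1
        etas.append(getattr(agent, "last_eta", np.nan))
        tds.append(abs(getattr(agent, "last_td", np.nan)))
        state = t.next_state
        if t.terminal or t.truncated:
            reached = env.goal_reached(t)
            break
    return EpisodeResult(
        total_reward=total,
        steps=steps,
        reached_goal=reached,
        ideal=reached and negatives == 0,
        epsilon=getattr(agent, "epsilon", float("nan")),
        mean_eta=float(np.mean(etas)),
        mean_abs_td=float(np.mean(tds)),
    )


def run_learning(env: Environment, agent, episodes: int, seed: int,
                 snapshot_every: int | None = None,
                 record: RunRecord | None = None) -> RunRecord:
    """Run ``episodes`` learning episodes; environment resets draw from the
    'env' stream of ``seed``. Appends to ``record`` when given (used by the
    sequential protocol to carry the agent across worlds)."""
    env_rng = stream_rng(seed, "env")
    rec = record if record is not None else RunRecord(seed=seed)
    for ep in range(episodes):
        rec.results.append(run_episode(env, agent, env_rng))
        if snapshot_every and (ep + 1) % snapshot_every == 0:
            rec.snapshots.append((len(rec.results) - 1, agent.snapshot()))
    return rec


def compare_agents(worlds: list, agent_factories: dict, repeats: int,
                   episodes: int, max_steps: int, base_seed: int,
                   ) -> ComparisonSummary:
    """End-of-learning comparison across worlds.

    ``agent_factories`` maps agent name -> callable(env_spec, seed) ->
    agent. Repeat r of every agent on every world uses seed
    ``base_seed + r`` so the comparison shares randomness.
    """
    if not worlds:
        raise ValueError("need at least one world")
    names = list(agent_factories)
    metrics = {"cumulative_reward": np.zeros((len(worlds), len(names))),
               "ideal_episodes": np.zeros((len(worlds), len(names)))}
    for wi, world in enumerate(worlds):
        for ai, name in enumerate(names):
            finals_r, finals_i = [], []
            for r in range(repeats):
                seed = base_seed + r
                env = GridWorldEnv(world, max_steps=max_steps)
                agent = agent_factories[name](env.spec, seed)
                rec = run_learning(env, agent, episodes, seed)
                finals_r.append(rec.final_cumulative_reward)
                finals_i.append(rec.final_cumulative_ideal)
            metrics["cumulative_reward"][wi, ai] = np.mean(finals_r)
            metrics["ideal_episodes"][wi, ai] = np.mean(finals_i)
    wins = {}
    for metric, table in metrics.items():
        tally = dict.fromkeys(names, 0.0)
        for row in table:
            best = row.max()
            top = [names[i] for i in np.flatnonzero(row == best)]
            for name in top:
                tally[name] += 1.0 / len(top)
        wins[metric] = tally
    return ComparisonSummary(names, metrics, wins)


def sequential_maze_protocol(world_a: GridWorld, world_b: GridWorld,
                             episodes_each: int, agent_factory, seed: int,
                             max_steps: int = 1000,
                             snapshot_every: int | None = None) -> RunRecord:
    """Learn on world A then, with agent state carried over, on world B."""
    if (world_a.width, world_a.height) != (world_b.width, world_b.height):
        raise ValueError("sequential worlds must share dimensions")
    env_a = GridWorldEnv(world_a, max_steps=max_steps)
    agent = agent_factory(env_a.spec, seed)
    rec = run_learning(env_a, agent, episodes_each, seed,
                       snapshot_every=snapshot_every)
    rec.switch_episode = episodes_each
    env_b = GridWorldEnv(world_b, max_steps=max_steps)
    run_learning(env_b, agent, episodes_each, seed,
                 snapshot_every=snapshot_every, record=rec)
    return rec


# ---------------------------------------------------------------------------
# Test oracles and SOM introspection
# ---------------------------------------------------------------------------

def value_iteration(world: GridWorld, gamma: float = 0.99, tol: float = 1e-10,
                    terminate_on_negative: bool = False) -> np.ndarray:
    """Exact optimal action values under the grid dynamics.

    Returns Q of shape (width, height, 4); the goal cell is absorbing with
    Q = 0. Sweeps the Bellman optimality operator to a ``tol`` max-norm
    fixed point.
    """
    q = np.zeros((world.width, world.height, 4))
    cells = [(x, y) for x in range(world.width) for y in range(world.height)
             if (x, y) != world.goal_cell]
    while True:
        q_new = np.zeros_like(q)
        for (x, y) in cells:
            for a in ACTIONS:
                t = grid_step(world, (x, y), a,
                              terminate_on_negative=terminate_on_negative)
                nx, ny = int(t.next_state[0]), int(t.next_state[1])
                cont = 0.0 if t.terminal else gamma * q[nx, ny].max()
                q_new[x, y, a] = t.reward + cont
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new


def greedy_rollout(world: GridWorld, q: np.ndarray, max_steps: int = 1000,
                   ) -> EpisodeResult:
    """Roll out the greedy policy of a Q table from the start cell."""
    pos = world.start_cell
    total, steps, negatives = 0.0, 0, 0
    while steps < max_steps:
        a = int(np.argmax(q[pos[0], pos[1]]))
        t = grid_step(world, pos, a)
        total += t.reward
        steps += 1
        if t.reward < 0:
            negatives += 1
        pos = (int(t.next_state[0]), int(t.next_state[1]))
        if t.terminal:
            return EpisodeResult(total, steps, True, negatives == 0)
    return EpisodeResult(total, steps, False, False)


def som_location_map(snapshot: dict, world: GridWorld) -> np.ndarray:
    """Bin each SOM unit's (inverse-normalized) weight vector to its nearest
    grid cell; returns per-cell unit counts of shape (width, height)."""
    from .som import RangeNormalizer

    weights = np.asarray(snapshot["unit_weights"], dtype=float)
    if weights.shape[1] != 2:
        raise ValueError("location maps require a 2-dimensional state space")
    if "normalizer" in snapshot:
        norm = RangeNormalizer.from_state_dict(snapshot["normalizer"])
        coords = np.stack([norm.denormalize(w) for w in weights])
    else:
        coords = weights
    counts = np.zeros((world.width, world.height), dtype=int)
    xs = np.clip(np.rint(coords[:, 0]).astype(int), 0, world.width - 1)
    ys = np.clip(np.rint(coords[:, 1]).astype(int), 0, world.height - 1)
    for x, y in zip(xs, ys):
        counts[x, y] += 1
    return counts
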