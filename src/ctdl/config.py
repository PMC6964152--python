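"""Experiment configuration: YAML in, validated dataclasses out.

Defaults are the published hyper-parameter tables: the grid-world run
lengths (W=H=10, E=1000, T=1000), the network block (layers [128, 128],
C=10000, B=32, RMSProp lr .00025 / momentum .95 / denominator constant
.01), the SOM block (36 units, tau_eta=10, tau_delta=1, sigma=.1,
sigma_c=.1, alpha=.01, rho=.9), the DQN buffer (M=100000), gamma=.99,
and the A2C Adam rates (critic .0001, actor .00001). Unknown keys are
rejected with the path to the offending field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["EnvironmentConfig", "AgentConfig", "RunConfig",
           "ExperimentConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown key {path}.{key}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.type in ("int",) and isinstance(value, bool):
            raise ConfigError(f"{path}.{f.name}: expected int, got bool")
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class EnvironmentConfig:
    name: str = "gridworld"           # gridworld | cartpole | mountaincar
    width: int = 10                   # W
    height: int = 10                  # H
    max_steps: int = 1000             # T (500 for cart-pole)
    symmetric: bool = True
    terminate_on_negative: bool = False
    layout: str | None = None         # named layout or JSON file path

    def __post_init__(self):
        if self.name not in ("gridworld", "cartpole", "mountaincar"):
            raise ValueError(f"environment.name: unknown environment {self.name!r}")
        if self.max_steps <= 0:
            raise ValueError("environment.max_steps must be positive")


@dataclass
class AgentConfig:
    name: str = "ctdl"                # ctdl | dqn | a2c | ctdl_a2c
    gamma: float = 0.99
    hidden: tuple = (128, 128)        # U without the output layer
    target_sync: int = 10_000         # C
    batch_size: int = 32              # B
    lr: float = 0.00025               # lambda (RMSProp)
    kappa: float = 0.95               # RMSProp momentum
    denom_const: float = 0.01         # phi
    som_units: int = 36               # U_som
    tau_eta: float = 10.0
    tau_delta: float = 1.0
    sigma: float = 0.1
    sigma_const: float = 0.1          # sigma_c
    alpha: float = 0.01
    rho: float = 0.9
    buffer_size: int = 100_000        # M (DQN)
    critic_lr: float = 0.0001         # Adam, A2C critic
    actor_lr: float = 0.00001         # Adam, A2C actor
    epsilon_start: float = 1.0
    epsilon_floor: float = 0.1
    epsilon_anneal: int = 200
    replay_enabled: bool = True
    som_learning_enabled: bool = True
    eta_override: float | None = None
    target_mode: str = "fused"

    def __post_init__(self):
        if self.name not in ("ctdl", "dqn", "a2c", "ctdl_a2c"):
            raise ValueError(f"agent.name: unknown agent {self.name!r}")
        for rate in ("gamma", "lr", "kappa", "denom_const", "tau_eta",
                     "tau_delta", "sigma", "sigma_const", "alpha", "rho",
                     "critic_lr", "actor_lr"):
            if getattr(self, rate) <= 0:
                raise ValueError(f"agent.{rate} must be positive")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("agent.gamma must lie in (0, 1)")
        self.hidden = tuple(self.hidden)


@dataclass
class RunConfig:
    seed: int = 0
    repeats: int = 1                  # full protocol: 30 per maze
    episodes: int = 1000              # E
    snapshot_every: int | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.repeats < 1 or self.episodes < 1:
            raise ValueError("run.repeats and run.episodes must be >= 1")


@dataclass
class ExperimentConfig:
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    agent: AgentConfig = field(default_factory=AgentConfig)
    run: RunConfig = field(default_factory=RunConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        if not isinstance(data, dict):
            raise ConfigError("top level: expected a mapping")
        known = {"environment", "agent", "run"}
        for key in data:
            if key not in known:
                raise ConfigError(f"unknown key {key}")
        return cls(
            environment=_from_dict(EnvironmentConfig,
                                   data.get("environment", {}), "environment"),
            agent=_from_dict(AgentConfig, data.get("agent", {}), "agent"),
            run=_from_dict(RunConfig, data.get("run", {}), "run"),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["agent"]["hidden"] = list(d["agent"]["hidden"])
        return d


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config, filling defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return ExperimentConfig.from_dict(data)


def dump_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write the fully resolved config (the echo kept beside outputs)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
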