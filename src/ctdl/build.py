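"""Factories mapping validated configs onto environments and agents."""

from __future__ import annotations

from pathlib import Path

from .agents.a2c import A2CAgent, CTDLA2CAgent
from .agents.ctdl import CTDLAgent
from .agents.dqn import DQNAgent
from .agents.schedules import EpsilonSchedule
from .config import AgentConfig, EnvironmentConfig
from .envs.base import Environment, EnvSpec
from .envs.cartpole import CartPoleEnv
from .envs.gridworld import (GridWorld, GridWorldEnv, generate_grid_world,
                             one_obstacle_maze, two_obstacle_maze,
                             upwards_maze)
from .envs.mountaincar import MountainCarEnv
from .seeding import stream_rng

__all__ = ["build_env", "build_agent", "named_layout"]

_LAYOUTS = {
    "upwards": upwards_maze,
    "one_obstacle": one_obstacle_maze,
    "two_obstacle": two_obstacle_maze,
}


def named_layout(name: str) -> GridWorld:
    if name not in _LAYOUTS:
        raise ValueError(f"unknown layout {name!r}; options: {sorted(_LAYOUTS)}")
    return _LAYOUTS[name]()


def build_env(cfg: EnvironmentConfig, seed: int) -> Environment:
    if cfg.name == "cartpole":
        return CartPoleEnv(max_steps=cfg.max_steps)
    if cfg.name == "mountaincar":
        return MountainCarEnv(max_steps=cfg.max_steps)
    if cfg.layout is not None:
        if cfg.layout in _LAYOUTS:
            world = named_layout(cfg.layout)
        else:
            world = GridWorld.from_json(Path(cfg.layout).read_text())
    else:
        world = generate_grid_world(cfg.width, cfg.height, cfg.symmetric,
                                    stream_rng(seed, "world"))
    return GridWorldEnv(world, max_steps=cfg.max_steps,
                        terminate_on_negative=cfg.terminate_on_negative)


def build_agent(cfg: AgentConfig, env_spec: EnvSpec, seed: int):
    schedule = EpsilonSchedule(cfg.epsilon_start, cfg.epsilon_floor,
                               cfg.epsilon_anneal)
    if cfg.name == "ctdl":
        return CTDLAgent(
            env_spec, seed, hidden=cfg.hidden, som_units=cfg.som_units,
            gamma=cfg.gamma, target_sync=cfg.target_sync, lr=cfg.lr,
            kappa=cfg.kappa, denom_const=cfg.denom_const,
            batch_size=cfg.batch_size, tau_eta=cfg.tau_eta,
            tau_delta=cfg.tau_delta, sigma=cfg.sigma,
            sigma_const=cfg.sigma_const, alpha=cfg.alpha, rho=cfg.rho,
            epsilon_schedule=schedule, replay_enabled=cfg.replay_enabled,
            som_learning_enabled=cfg.som_learning_enabled,
            eta_override=cfg.eta_override, target_mode=cfg.target_mode,
        )
    if cfg.name == "dqn":
        return DQNAgent(
            env_spec, seed, hidden=cfg.hidden, gamma=cfg.gamma,
            target_sync=cfg.target_sync, lr=cfg.lr, kappa=cfg.kappa,
            denom_const=cfg.denom_const, batch_size=cfg.batch_size,
            buffer_size=cfg.buffer_size, epsilon_schedule=schedule,
        )
    if cfg.name == "a2c":
        return A2CAgent(env_spec, seed, hidden=cfg.hidden, gamma=cfg.gamma,
                        critic_lr=cfg.critic_lr, actor_lr=cfg.actor_lr)
    return CTDLA2CAgent(
        env_spec, seed, hidden=cfg.hidden, gamma=cfg.gamma,
        critic_lr=cfg.critic_lr, actor_lr=cfg.actor_lr,
        som_units=cfg.som_units, tau_eta=cfg.tau_eta,
        tau_delta=cfg.tau_delta, sigma=cfg.sigma,
        sigma_const=cfg.sigma_const, alpha=cfg.alpha, rho=cfg.rho,
        eta_override=cfg.eta_override,
    )
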