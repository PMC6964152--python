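# ctdl

Complementary temporal-difference learning: a reinforcement-learning agent
that pairs a slowly trained Q-network with a fast, surprise-gated
self-organizing map (SOM) memory, in the spirit of complementary learning
systems theory — a "neocortical" learner that generalizes and a
"hippocampal" learner that stores pattern-separated exceptions. The package
is for researchers in computational neuroscience and reinforcement learning
who want a small, fully inspectable implementation of the agent, its
baselines (DQN, online A2C), its continuous-action extension, and the
benchmark tasks they are compared on.

## The model

At state *s* the agent retrieves the best-matching unit (BMU) *u* of a
square-lattice SOM whose unit weights β<sub>u</sub> live in normalized
[0, 1] state space, and computes a fusion weight from the retrieval
distance *d* = ‖β<sub>u</sub> − s̃‖₂:

    η = exp(−τ_η · d)

Action values are the η-weighted average of the SOM's stored table and the
network's prediction:

    Q(s, a) = η · Q_SOM(u, a) + (1 − η) · Q_DNN(s, a)

and the behaviour policy is ε-greedy over the fused values. Learning is
driven by the network's TD error δ<sub>TD</sub> = y − Q_DNN(s, a) with
bootstrapped target y = r + γ max<sub>a′</sub> Q(s′, a′) (network part
read from a periodically synchronized target copy; y = r at terminal
states). Each transition:

1. one RMSProp gradient step of the online network toward *y* on the taken
   action (mean-squared TD error objective);
2. a plasticity gain δ = 1 − exp(−|δ<sub>TD</sub>|/τ_δ) scales **both** the
   SOM learning rate and the width of its lattice neighbourhood
   (δ·σ + σ_c), so the map only recruits units for states the network is
   bad at evaluating;
3. the BMU retrieved when the action was chosen has its stored value moved
   toward *y* with step ρ·η — large updates only for close matches;
4. the SOM's contents (unit weight vectors and their stored values) are
   replayed to the network as a training batch, standing in for
   hippocampal-to-neocortical replay. No transition buffer is kept.

`CTDLA2CAgent` extends the scheme to continuous actions: the SOM stores
scalar state values fused with an actor–critic's critic, and the critic's
TD error both gates SOM plasticity and serves as the advantage for a
Gaussian-policy actor.

## Worked example

```python
import numpy as np
from ctdl import (CTDLAgent, DQNAgent, GridWorldEnv, EpsilonSchedule,
                  run_learning, upwards_maze, two_obstacle_maze)

world = two_obstacle_maze()          # 10x10, two staggered hazard walls
env = GridWorldEnv(world, max_steps=200)
agent = CTDLAgent(env.spec, seed=1, hidden=(32, 32), som_units=16)
record = run_learning(env, agent, episodes=150, seed=1)
print(f"cumulative reward {record.final_cumulative_reward:.1f}, "
      f"ideal episodes {record.final_cumulative_ideal}")
```

This prints (seed 1):

```
cumulative reward -1405.0, ideal episodes 0
```

i.e. over 150 short episodes on the hard two-wall maze the agent is still
early in learning — it accrues −1405 total reward (negative cells cost
−1 each entry) and completes no *ideal* episode yet (an episode that
reaches the goal without touching a single negative cell). The same
protocol on the obstacle-free corridor maze yields dozens of ideal
episodes; the interesting quantity is the *comparison* between agents and
mazes, not any single run.

The command-line interface mirrors the library:

```
ctdl run --env gridworld --agent ctdl --seed 1 --out out/
ctdl compare --agents ctdl,dqn --worlds 5 --repeats 3
ctdl sequential --agent ctdl --layout-a upwards --layout-b one_obstacle --out out/
ctdl ablation --mode no_replay --out out/
```

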