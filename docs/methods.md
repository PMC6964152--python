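# Methods

## Model overview

The agent couples two value learners that operate in parallel and are
fused at decision time:

- **Network half.** A fully connected network (ReLU hidden layers, linear
  output; one output per action) trained by RMSProp on the mean squared
  TD error. A frozen copy provides bootstrap targets and is refreshed
  every `target_sync` environment steps. Gradients are computed by
  hand-rolled reverse-mode differentiation (`ctdl.nn`); there is no
  autodiff dependency.
- **Memory half.** A square-lattice SOM (`ctdl.som`). Each unit u has a
  weight vector β_u in normalized state space and a value record —
  a per-action table Q(u, a), or a scalar V(u) in critic mode.

Fusion: Q(s, ·) = η · Q_SOM(bmu, ·) + (1 − η) · Q_DNN(s, ·), with
η = exp(−τ_η · d) and d the euclidean BMU distance in normalized space.
Plasticity gating: δ = 1 − exp(−|TD|/τ_δ) multiplies both the SOM weight
learning rate (α · δ) and the neighbourhood width (δ·σ + σ_c) of the
squared-exponential lattice kernel. Value learning:
Q_SOM(u, a) ← Q_SOM(u, a) + ρ · η · (y − Q_SOM(u, a)), applied to the BMU
cached when the action was selected, using the η cached at the same
moment. Each step one batch of SOM contents (states = unit weights mapped
back to raw space, targets = stored values, actions uniform) is replayed
to the network.

### Functional-form choices

The η, δ and neighbourhood kernels are described qualitatively in the
source literature (a temperature-scaled distance decay; an exponentially
saturating function of |TD|; a TD-modulated neighbourhood), not as
formulas. The forms implemented here — η = exp(−τ_η·d) (a
squared-exponential variant is available via `eta_squared`),
δ = 1 − exp(−|TD|/τ_δ), and φ(u) = exp(−‖p_u − p_bmu‖² / (2(δσ + σ_c)²))
on integer lattice coordinates — satisfy every stated qualitative
property: η(0) = 1, η strictly decreasing, δ(0) = 0, δ strictly
increasing and bounded by 1, zero plasticity at zero TD error, σ_c
preventing a degenerate kernel at δ = 0. They are conventions of this
package, tested as such.

### Timing convention

A learning step processes the transition (s, a, r, s′). The target
y = r + γ · max fused-Q(s′) (y = r at terminal s′; truncation by the step
cap still bootstraps from s′). The TD error is measured against the
*online* network's Q(s, a); the network part of the bootstrap comes from
the *target* copy, while SOM values are read live. The SOM weight update
moves toward s (the state whose evaluation produced the TD error), and
the value update targets the BMU/η cached when a was selected at s. In
the degenerate configuration (η ≡ 1, one unit pinned per grid cell,
frozen map, replay off) this reduces exactly to tabular Q-learning with
rate ρ — the test suite verifies this against an independent tabular
implementation and against value iteration.

An alternative bootstrap using only the target network's maximum (not the
fused value) is available via `target_mode="dnn"`.

## Normalization

States are normalized per dimension to [0, 1] using an online min/max
record before any SOM distance computation, for every environment (the
motivation is scale balance between dimensions, acute for cart-pole
velocities; applying it uniformly makes τ_η scale-free). The network
always consumes raw states; replayed SOM states are mapped back through
the inverse record. A dimension with no observed range yet maps to 0.5,
and its inverse returns the single observed value.

## Environments

- **Grid world** (`ctdl.envs.gridworld`): W×H cells, deterministic
  four-action moves, off-grid moves leave the agent in place. One goal
  (+1, absorbing), floor(W·H/5) negative cells (−1 per entry,
  non-terminal by default; `terminate_on_negative` flips this — the
  episode-end rule in the source describes only the goal). Symmetric
  generation samples negatives as mirror pairs about the vertical
  midline (plus midline singletons when the width is odd; an even width
  with an odd target count is rejected as infeasible) and places start
  and goal on the midline column(s); layouts whose goal is unreachable
  through non-negative cells are resampled (breadth-first check). Three
  fixed 10×10 benchmark layouts — an obstacle-free upwards corridor, a
  one-wall maze, and a two-staggered-wall maze — are *reconstructions*
  of published figures whose exact cell lists are not available; each
  keeps 20 negative cells and mirror symmetry.
- **Cart-pole** (`ctdl.envs.cartpole`): classic-control constants
  (gravity 9.8, cart mass 1.0, pole mass 0.1, half-length 0.5, force
  ±10 N, Euler step 0.02 s, track bound ±2.4), failure angle 15°
  (deliberately wider than the common 12°), +1 reward per step,
  truncation at 500 steps.
- **Mountain car** (`ctdl.envs.mountaincar`): force coefficient 0.0015,
  gravity coefficient 0.0025, position ∈ [−1.2, 0.6], |velocity| ≤ 0.07,
  target 0.45, start uniform in [−0.6, −0.4] at rest. Reward −force² per
  step (coefficient 1, configurable) and +100 on reaching the target;
  truncation at 1000 steps.

Truncation is flagged separately from terminal so bootstrap targets
still use the next state when an episode merely hits the cap.

## Default hyper-parameters

All defaults (see `ctdl.config`) are the published table values: γ = 0.99;
network [128, 128] hidden, C = 10000 (500 recommended for cart-pole's
shorter episodes), batch 32, RMSProp λ = 0.00025 / κ = 0.95 / φ = 0.01;
SOM 36 units (225 for cart-pole, 16 for the benchmark layout figures),
τ_η = 10, τ_δ = 1, σ = σ_c = 0.1, α = 0.01, ρ = 0.9; DQN buffer
M = 100000; ε annealed 1.0 → 0.1 over the first 200 episodes; A2C Adam
rates 1e-4 (critic) / 1e-5 (actor). Unspecified conventions: ReLU hidden
activations, uniform ±1/√fan-in weight initialization on hidden layers
with the *output layer initialized at zero*, zero biases, SOM unit
weights initialized uniform in [0,1]^d, value records at zero, the
actor's spread head softplus-transformed and clamped to [0.01, 1], no
entropy bonus.

The zero output layer matters: value networks here consume raw
(unnormalized) states, so a randomly initialized output layer predicts
values of magnitude well above the task's reward scale, and the
γ·max bootstrap then chases the positive bias of a random function for
an entire target-sync interval — enough to bake in inflated values and
absorbing greedy loops. Starting from Q ≡ 0 makes the first targets
equal the observed rewards and removes the pathology; ε-greedy
tie-breaking supplies the initial exploration that random initial Q
values would otherwise provide.

## Scaled study conditions

The full comparison protocol (50 worlds × 30 repeats × 1000 episodes) is
hours long; routine runs and `scripts/acceptance.py` use the scaled
conditions in `ctdl.experiments.SCALED_GRID_PROFILE`: 150 episodes,
200-step cap, hidden widths (32, 32), 16 SOM units, 5 repeats, every
other hyper-parameter at its published value. The sequential maze-switch
protocol needs the exploration anneal to finish inside the first phase
(in the full protocol it occupies the first 40% of the pre-switch
phase), so the scaled version uses 200-episode phases with the anneal
over the first 80 episodes — the same fraction.

At this scale the comparisons probe *early* learning: the directional
outcomes (DQN ahead on the generalizable corridor maze, the fused agent
ahead on rule-violating mazes and after an environment switch) emerge,
but absolute ideal-episode counts are far below full-scale values, and
on the hardest maze both agents may record zero ideal episodes while
still differing in cumulative reward. Passing scaled checks shows the
mechanism ranks the agents as expected early in learning, not that
full-scale curves are reproduced.

## Randomness and reproducibility

One root seed fans out into named streams (`env`, `net_init`, `som_init`,
`policy`, `replay`, …) via `ctdl.seeding`, so ablations that remove one
consumer (e.g. replay) leave all other draws untouched and runs are
bitwise reproducible from (config, seed). ε-greedy selection always
consumes exactly two draws, which keeps trajectories of different agent
variants comparable under shared seeds; argmax ties break uniformly at
random, best-matching-unit ties break to the lowest unit index.

## Known limitations

- Observations are low-dimensional state vectors; there is no image
  pipeline or embedding front-end.
- The benchmark maze layouts are topological reconstructions, not exact
  reproductions.
- Scaled-condition outcomes are directional; variance across seeds is
  substantial and 5 repeats only support mean comparisons, not
  significance statements.
- The A2C implementation is the strictly online, single-worker variant;
  no entropy regularization, n-step returns or parallel rollouts.
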