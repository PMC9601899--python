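# bnbot

Simulation and analysis toolkit for robots controlled by **random Boolean
networks (RBNs)** that adapt online, studying how a controller's dynamical
regime — ordered, critical ("edge of chaos") or chaotic — shapes its ability
to learn sensorimotor tasks.

A Boolean network with `n` nodes, `k = 3` distinct random sources per node
and truth tables drawn with bias `p` acts as the robot's controller: sensor
readings are binarized and overwrite designated input nodes, the network
performs one synchronous update per control step, and two (or three)
output nodes drive the wheels (and, in the foraging task, a gripper hook).
Between fixed-length epochs an adaptation mechanism proposes a change and
keeps it only if the epoch score did not decrease.

## What is in the box

| Module | Purpose |
|---|---|
| `bnbot.rbn` | RBN generation (bias-parameterized ensembles), synchronous update, serialization |
| `bnbot.derrida` | One-step Derrida value λ (perturbation spreading), regime classification, annealed approximation λ = 2p(1−p)k |
| `bnbot.arena` | 2-D differential-drive simulation: arenas, obstacles, 24 proximity + 24 light sensors, collision handling |
| `bnbot.coupling` | Sensor binarization and the input/output node mapping between network and robot |
| `bnbot.objectives` | Scores for the three tasks: navigation, region-bound navigation, foraging |
| `bnbot.adaptation` | The three online mechanisms — in-out mapping, mutation, hybrid — and the accept-if-not-worse epoch loop |
| `bnbot.drift` | Null model: regime drift under mutation alone (no selection), Monte Carlo + closed form |
| `bnbot.analysis` | Mean-of-max curves, AUC, mean ranks, nominal-vs-actual regime assignment, rank-sum tests |
| `bnbot.experiment` | Full sweep orchestration (tasks × mechanisms × biases × runs), CSV/JSON artifacts |

A `bnbot` command-line interface exposes `generate`, `run`, `derrida`,
`drift` and `analyze` subcommands.

## Worked example

```python
import numpy as np
from bnbot import EnsembleSpec, generate_rbn
from bnbot.derrida import derrida_states, annealed_lambda, classify_regime
from bnbot.adaptation import make_robot_config, adapt
from bnbot.arena import arena_task1

# 1. Generate a critical-bias network and measure its Derrida value
spec = EnsembleSpec(n=200, k=3, p=0.21, seed=42)
net = generate_rbn(spec)
rng = np.random.default_rng(42)
states = rng.integers(0, 2, size=(50, 200), dtype=np.uint8)
lam = derrida_states(net, states, rng=rng).mean()
print(f"measured lambda = {lam:.3f} (annealed prediction {annealed_lambda(0.21, 3):.3f})")
print(f"regime: {classify_regime(lam)}")

# 2. Adapt two robots on the navigation task via in-out mapping
rng = np.random.default_rng(2)
configs = [make_robot_config(spec, task=1, rng=rng) for _ in range(2)]
records = adapt(arena_task1(), configs, task=1, mechanism="in-out-mapping",
                epochs=30, steps=800, seed=2)
for i, rec in enumerate(records):
    print(f"robot {i}: epoch-0 score {rec.scores[0]:.2f} -> "
          f"best {rec.best_score:.2f} (epoch {rec.best_epoch})")
```

Output:

```
measured lambda = 0.998 (annealed prediction 0.995)
regime: critical
robot 0: epoch-0 score 0.12 -> best 53.64 (epoch 21)
robot 1: epoch-0 score 0.12 -> best 52.75 (epoch 20)
```

The measured λ of a freshly generated p = 0.21 ensemble sits at the critical
value 1; thirty epochs of remapping which nodes the sensors and wheels touch
— the network itself bit-unchanged — lifts the navigation score from ≈ 0 to
≈ 53 out of 100.

## Documentation

Methods, parameter defaults and their rationale, and known limitations are
documented in [docs/methods.md](docs/methods.md).
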