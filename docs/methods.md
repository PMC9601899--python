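# Methods

This note records how each model component is defined, the default
parameter values, why they were chosen, and where the implementation is
known to diverge from the physical-robot setting it emulates.

## Random Boolean networks

A network has `n` nodes; each node reads `k = 3` distinct source nodes,
never including itself, chosen uniformly at random. Truth tables are
`2^k`-entry bit vectors drawn i.i.d. Bernoulli(`p`); `p` is the
*generation bias*. Updates are synchronous: all nodes read the previous
global state and write the next one simultaneously. Truth-table rows are
indexed big-endian — the **first** source is the most significant bit.

Bias determines the nominal dynamical regime of the ensemble (`k = 3`):

| bias p | nominal regime |
|---|---|
| 0.1, 0.9 | ordered |
| 0.21, 0.79 | critical |
| 0.5 | chaotic |

Nodes designated as actuator outputs are always regenerated with bias
0.5, whatever the network bias, so the wheels are not biased off or on at
birth. Default size is `n = 1000` (the mutation arithmetic below only
balances at that size).

## Derrida value and regime classification

The one-step Derrida value λ of a network at a state is the mean Hamming
distance, after one synchronous step, between the state's successor and
the successors of single-node-flipped copies. Per state we flip 100
distinct uniformly chosen nodes (all nodes when `n ≤ 100`). Classification
uses ε = 0.3: ordered if λ < 0.7, critical if 0.7 ≤ λ ≤ 1.3, chaotic if
λ > 1.3. The annealed (mean-field) approximation is λ = 2p(1−p)k; the test
suite checks measured ensembles agree with it within 3 standard errors.

A *trajectory-restricted* variant measures λ over the 800 states a robot's
network actually visited during its best epoch, with the network isolated
(no sensor overwriting), distinguishing *nominal* regime (from the
generation bias) from *actual* regime (measured after adaptation).

## Arena and robot physics

Differential-drive disc robot: wheel commands `l, r ∈ {0, 1}`;
`v = v_max (l + r) / 2`, `ω = v_max (r − l) / axle`. Rotation always
applies; translation is blocked entirely (position clamped, collision flag
raised) if the new position would intersect a wall, obstacle or another
robot. Robots update in fixed order within a step, sensing the previous
positions of the others.

Defaults (foot-bot-like values, fixed before any behavioural experiment
was run):

| parameter | value | rationale |
|---|---|---|
| control step `dt` | 0.1 s | 10 Hz control, 800 steps = 80 s epoch |
| `v_max` | 0.15 m/s | typical small-wheeled-robot cruise speed |
| wheel axle | 0.14 m | foot-bot body scale |
| body radius | 0.085 m | foot-bot footprint |
| proximity range | 0.10 m | short-range IR-style sensors |
| light range | 6.0 m | covers the foraging arena |
| light falloff | linear | simple monotone gradient (inverse-square optional) |

Arenas (geometry not published; chosen as plausible and fixed up front):

- **Task I (navigation):** 4 m square, one 1 m square obstacle at the
  center.
- **Task II (region-bound navigation):** 5 × 3 m rectangle split at
  x = 0 into left/right halves; each robot is assigned the half it starts
  in.
- **Task III (foraging):** regular octagon, circumradius 2.5 m; blue
  (pickup) zone x < −1.3, green (deposit) zone x ≥ 1.3; two 0.8 m square
  obstacles at (0, ±0.9); light source at the east-face midpoint as a
  beacon toward the green zone.

Sensing: 24 proximity rays and 24 light sensors at equally spaced body
angles. A proximity reading is `clip(1 − (d − radius)/range, 0, 1)` for
hit distance `d`; light readings combine source intensity with the
cosine-clamped alignment of each sensor. The collision measure θ of a
step is the maximum of the 24 proximity readings.

## Sensor/actuator coupling

The 24 proximity (and, in task III, light) readings are reduced in groups
of 3 by maximum and binarized with a **strict** threshold of 0.1, giving
8 Booleans per modality. Task II adds one bit: "currently in the assigned
region". Task III adds a 2-bit region code (neutral 00, green 01, blue
10). Input counts per task: 8 / 9 / 18; outputs: 2 wheels (+1 hook in
task III). Input values overwrite their nodes before each synchronous
step; outputs are read after it.

## Objectives

Epoch length E = 800 steps. With θ the collision measure and `l, r` the
wheel bits:

- **Task I:** `(100/E) Σ (1−θ)(1−|l−r|)(l+r)/2` — fast, straight,
  collision-free motion; maximum 100.
- **Task II:** the same summand multiplied by ε = +1 inside the robot's
  assigned region, −1 outside.
- **Task III:** `(100/E) Σ [ρ + (1−2θ)(1−|l−r|)(l+r)/2]` — the movement
  term with a doubled collision penalty (it can go negative) plus event
  rewards ρ: +50 picking up in blue (hook raised while empty), +50
  depositing in green (hook lowered while carrying), −100 depositing
  elsewhere. The hook is edge-triggered on the third output bit.

## Adaptation

Each epoch ends with a proposal; the first epoch evaluates the initial
random configuration as the baseline. A proposal is kept iff its score is
**not worse** than the incumbent's (sideways moves accepted); rejection
restores the previous configuration bit-exactly.

- **In-out mapping:** re-draw 2 input channels and 1 output channel onto
  unused nodes; the network itself is never modified.
- **Mutation:** flip exactly 80 truth-table bits and rewire exactly 30
  arcs at n = 1000 — both 1% of their totals; at other sizes the counts
  scale as `round(0.01·n·2^k)` and `round(0.01·n·k)`. A rewired arc's new
  source excludes the node itself, its other sources and the current
  source, so every rewiring changes the wiring.
- **Hybrid:** both in one proposal.

Seeding is hierarchical (`numpy` `SeedSequence`): one master seed spawns
placement and per-robot streams, each of which spawns per-epoch streams,
so any robot's trajectory is reproducible in isolation. Robots continue
from their end-of-epoch pose (only the score is reset); reset-to-start is
available as an option.

## Drift null model

Applying mutation alone (no selection) each epoch performs an unbiased
random walk on truth-table bits: each bit flips with probability
q = 80/8000 = 0.01 per epoch, so the mean bias relaxes as
`b_t = 0.5 + (b_0 − 0.5)(1 − 2q)^t` and λ_t = 2 b_t (1 − b_t) k. An
initially ordered ensemble (p₀ = 0.1) crosses into all-chaotic
classification around epoch 45 (measured; the analytic bound is ≈ 200 for
the mean to come within ε of 1.5's band edge). The module provides both
the Monte-Carlo simulation and the closed form; their agreement is a
tested property.

## Analysis

Per condition (mechanism × bias), the headline curve is the
**mean-of-max**: each robot's cumulative best score per epoch, averaged
over robots and runs. Conditions are ranked by the curve's AUC (unit-step
sum) and by the mean global rank of robots' final best scores (descending
ranks, ties averaged). Group comparisons use the Wilcoxon rank-sum test
(`scipy.stats.ranksums`). Regime assignment compares nominal (bias-based)
with actual (trajectory-measured λ) regimes.

## Known divergences and limitations

- **Foraging regime ordering is reversed at desk scale.** The published
  behavioural result — chaotic (p = 0.5) controllers scoring below
  critical (p = 0.21) — reproduces for navigation (task I) only after
  ≈ 100 epochs at n = 200, and does **not** reproduce for foraging
  (task III) in any configuration probed (n = 200 or 1000, 2 or 10
  robots, up to 100 epochs): chaotic stays well ahead. Cause: under the
  hard collision stop, a critical robot near a wall sees θ ≈ 1, making
  any movement score-negative, so freezing is a local optimum that
  accept-if-not-worse cannot leave; chaotic jitter keeps accumulating
  movement score. Physical robots presumably slid along or recovered
  from contacts instead of stopping dead. The corresponding acceptance
  test is left failing rather than weakened.
- Arena geometry, sensor ranges and kinematic constants are plausible
  reconstructions, not published values.
- Robots are discs; wheel commands are Boolean; sensor noise is absent.
- The trajectory-restricted Derrida measure isolates the network, so it
  reflects autonomous dynamics, not closed-loop dynamics under sensory
  overwriting.
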