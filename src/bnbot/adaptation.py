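"""Online adaptation: the epoch loop and the three adaptive mechanisms.

Each robot runs its Boolean network controller for an epoch of 800 control
steps, scores the epoch with the task objective, and keeps the current
configuration only if it is *not worse* than the previous retained one
(sideways moves allowed); otherwise the previous configuration is restored
exactly.  Three proposal mechanisms are available:

* ``in-out-mapping`` -- reassign two sensor channels and one actuator
  channel to fresh nodes; the network itself is never touched.
* ``mutation``       -- negate 1% of the truth-table entries (80 bits at
  n=1000, k=3) and redistribute 1% of the arcs (30 at n=1000, k=3); the
  coupling is never touched.
* ``hybrid``         -- both.

All robots in a run adapt concurrently in the same arena without sharing
information.  The first epoch evaluates the initial random configuration;
proposals start at the end of epoch 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from . import objectives
from .arena import (
    Arena,
    DEFAULT_PHYSICS,
    Physics,
    RobotState,
    collision_theta,
    light_readings,
    place_robots,
    proximity_readings,
    region_of,
    step_kinematics,
)
from .coupling import Coupling, build_coupling, encode_inputs, remap
from .objectives import EpochTrace, hook_action, reward_rule
from .rbn import BooleanNetwork, EnsembleSpec, generate_rbn, synchronous_step

__all__ = [
    "RobotConfig",
    "AdaptationRecord",
    "MECHANISMS",
    "mutate",
    "propose",
    "accept",
    "simulate_epoch",
    "adapt",
    "adapt_robot",
    "make_robot_config",
]

MECHANISM_ALIASES = {
    "io": "in-out-mapping",
    "in-out-mapping": "in-out-mapping",
    "mut": "mutation",
    "mutation": "mutation",
    "hyb": "hybrid",
    "hybrid": "hybrid",
}
MECHANISMS = ("in-out-mapping", "mutation", "hybrid")


def canonical_mechanism(name: str) -> str:
    try:
        return MECHANISM_ALIASES[name]
    except KeyError:
        raise ValueError(f"unknown mechanism {name!r}") from None


@dataclass
class RobotConfig:
    """The adaptable pair: a Boolean network and its sensor/actuator
    coupling."""

    network: BooleanNetwork
    coupling: Coupling

    def copy(self) -> "RobotConfig":
        return RobotConfig(self.network.copy(), self.coupling)


def make_robot_config(
    spec: EnsembleSpec, task: int, rng: np.random.Generator
) -> RobotConfig:
    """Sample a coupling, then a network whose actuator nodes get bias-0.5
    truth tables."""
    cpl = build_coupling(task, spec.n, rng)
    net = generate_rbn(spec, output_nodes=cpl.output_nodes, rng=rng)
    return RobotConfig(net, cpl)


def mutate(
    net: BooleanNetwork,
    rng: np.random.Generator,
    bit_fraction: float = 0.01,
    arc_fraction: float = 0.01,
    n_bits: int | None = None,
    n_arcs: int | None = None,
) -> BooleanNetwork:
    """Structural mutation: negate ``n_bits`` distinct truth-table entries
    (default 1% of n*2^k: 80 at n=1000, k=3) and give ``n_arcs`` distinct
    arcs (default 1% of n*k: 30) a new source.

    The new source of an arc is drawn uniformly among nodes that are not
    the arc's target, not one of the target's other sources and not the
    current source, so every rewired entry actually changes and per-node
    source distinctness and the no-self-loop rule are preserved.  Returns
    a new network; the input is untouched.
    """
    n, k = net.n, net.k
    if n_bits is None:
        n_bits = round(bit_fraction * n * 2**k)
    if n_arcs is None:
        n_arcs = round(arc_fraction * n * k)
    out = net.copy()
    flat_bits = rng.choice(n * 2**k, size=n_bits, replace=False)
    tab = out.truth_tables.reshape(-1)
    tab[flat_bits] ^= 1
    flat_arcs = rng.choice(n * k, size=n_arcs, replace=False)
    mask = np.empty(n, dtype=bool)
    for fa in flat_arcs:
        i, j = divmod(int(fa), k)
        mask[:] = True
        mask[i] = False
        mask[out.wiring[i]] = False
        out.wiring[i, j] = rng.choice(np.flatnonzero(mask))
    return out


def propose(
    config: RobotConfig,
    mechanism: str,
    rng: np.random.Generator,
    regen_output_tables: bool = False,
) -> RobotConfig:
    """Apply one adaptive move, returning a new configuration.

    ``regen_output_tables`` optionally redraws the truth table of a newly
    remapped output node at bias 0.5 (off by default: the in-out-mapping
    mechanism leaves the network bit-identical).
    """
    mechanism = canonical_mechanism(mechanism)
    net, cpl = config.network, config.coupling
    if mechanism in ("mutation", "hybrid"):
        net = mutate(net, rng)
    else:
        net = net.copy()
    if mechanism in ("in-out-mapping", "hybrid"):
        old_outputs = set(cpl.output_nodes)
        cpl = remap(cpl, net.n, rng)
        if regen_output_tables:
            for node in set(cpl.output_nodes) - old_outputs:
                net.truth_tables[node] = (
                    rng.random(2**net.k) < 0.5
                ).astype(np.uint8)
    return RobotConfig(net, cpl)


def accept(prev_score: float, new_score: float) -> bool:
    """Keep the new configuration iff it is not worse (sideways moves
    allowed)."""
    if math.isnan(prev_score) or math.isnan(new_score):
        raise ValueError("scores must not be NaN")
    return new_score >= prev_score


# -- epoch simulation ------------------------------------------------------


def simulate_epoch(
    arena: Arena,
    configs: list[RobotConfig],
    robots: list[RobotState],
    bn_states: list[np.ndarray],
    task: int,
    steps: int = 800,
    physics: Physics = DEFAULT_PHYSICS,
    record_states: bool = True,
) -> tuple[list[EpochTrace], list[RobotState], np.ndarray | None]:
    """Run all robots concurrently for one epoch.

    Per control step and robot: sense (proximity, light, region), encode to
    Booleans, overwrite the input nodes, synchronous network update, read
    the output nodes, actuate (differential drive + hook), record the
    per-step objective terms.  Robots are updated in fixed index order;
    ``bn_states`` is advanced in place.  Returns the per-robot traces, the
    end-of-epoch robot states and (optionally) the visited network states,
    shape (robots, steps, n).
    """
    R = len(configs)
    n = configs[0].network.n
    traces = [
        EpochTrace(
            theta=np.empty(steps),
            left=np.empty(steps),
            right=np.empty(steps),
            eps_region=np.empty(steps) if task == 2 else None,
            reward=np.zeros(steps) if task == 3 else None,
            action=[] if task == 3 else None,
            region=[],
        )
        for _ in range(R)
    ]
    visited = np.empty((R, steps, n), dtype=np.uint8) if record_states else None
    robots = list(robots)
    positions = np.array([[rb.x, rb.y] for rb in robots])
    in_idx = [np.array(c.coupling.input_nodes) for c in configs]
    out_idx = [np.array(c.coupling.output_nodes) for c in configs]
    for t in range(steps):
        for i in range(R):
            rob = robots[i]
            others = np.delete(positions, i, axis=0)
            prox = proximity_readings(arena, rob, others, physics)
            theta = collision_theta(prox)
            region = region_of(arena, rob)
            light = light_readings(arena, rob, physics) if task == 3 else None
            bits = encode_inputs(task, prox, light, region, rob.assigned_region)
            s = bn_states[i]
            s[in_idx[i]] = bits
            s = synchronous_step(configs[i].network, s)
            bn_states[i] = s
            if record_states:
                visited[i, t] = s
            out = s[out_idx[i]]
            l, r = float(out[0]), float(out[1])
            rob2 = step_kinematics(arena, rob, l, r, others, physics)
            tr = traces[i]
            tr.theta[t] = theta
            tr.left[t] = l
            tr.right[t] = r
            region_after = region_of(arena, rob2)
            tr.region.append(region_after)
            if task == 2:
                tr.eps_region[t] = (
                    1.0 if region_after == rob.assigned_region else -1.0
                )
            elif task == 3:
                hook = bool(out[2])
                action = hook_action(rob.hook, hook)
                rho, carrying = reward_rule(action, region_after, rob.carrying)
                tr.reward[t] = rho
                tr.action.append(action)
                rob2 = dc_replace(rob2, hook=hook, carrying=carrying)
            robots[i] = rob2
            positions[i, 0] = rob2.x
            positions[i, 1] = rob2.y
    return traces, robots, visited


@dataclass
class AdaptationRecord:
    """Per-robot outcome of an adaptation run."""

    scores: np.ndarray  # evaluated score per epoch
    accepted: np.ndarray  # whether each epoch's config was retained
    best_epoch: int
    best_score: float
    best_states: np.ndarray | None  # visited network states of the best epoch
    final_config: RobotConfig


def adapt(
    arena: Arena,
    configs: list[RobotConfig],
    task: int,
    mechanism: str,
    epochs: int = 500,
    steps: int = 800,
    seed: int | np.random.SeedSequence | None = None,
    robots: list[RobotState] | None = None,
    physics: Physics = DEFAULT_PHYSICS,
    reposition: bool = False,
    record_states: bool = True,
) -> list[AdaptationRecord]:
    """Adapt all robots concurrently for ``epochs`` epochs.

    Seed hierarchy: the run seed spawns a placement stream plus one stream
    per robot, from which per-epoch proposal streams are spawned, so a
    single robot's move sequence is reproducible in isolation.  Robots
    continue from their end-of-epoch pose unless ``reposition`` is set.
    """
    mechanism = canonical_mechanism(mechanism)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    R = len(configs)
    place_ss, *robot_ss = ss.spawn(R + 1)
    if robots is None:
        robots = place_robots(
            arena, R, np.random.default_rng(place_ss), physics,
            assign_regions=(task == 2),
        )
    init_robots = list(robots)
    bn_states = [c.network.state.copy() for c in configs]
    retained = [c.copy() for c in configs]
    current = retained
    prev_scores = [None] * R
    rec_scores = np.empty((R, epochs))
    rec_accept = np.zeros((R, epochs), dtype=bool)
    best_epoch = [0] * R
    best_score = [-np.inf] * R
    best_states: list[np.ndarray | None] = [None] * R
    for e in range(epochs):
        if reposition:
            robots = list(init_robots)
        traces, robots, visited = simulate_epoch(
            arena, current, robots, bn_states, task, steps, physics, record_states
        )
        for i in range(R):
            sc = objectives.score(task, traces[i])
            rec_scores[i, e] = sc
            if prev_scores[i] is None or accept(prev_scores[i], sc):
                rec_accept[i, e] = True
                retained[i] = current[i]
                prev_scores[i] = sc
            if sc > best_score[i]:
                best_score[i] = sc
                best_epoch[i] = e
                if record_states:
                    best_states[i] = visited[i].copy()
        if e < epochs - 1:
            current = [
                propose(
                    retained[i],
                    mechanism,
                    np.random.default_rng(robot_ss[i].spawn(1)[0]),
                )
                for i in range(R)
            ]
    return [
        AdaptationRecord(
            rec_scores[i],
            rec_accept[i],
            best_epoch[i],
            float(best_score[i]),
            best_states[i],
            retained[i],
        )
        for i in range(R)
    ]


def adapt_robot(
    config: RobotConfig,
    arena: Arena,
    task: int,
    mechanism: str,
    epochs: int = 500,
    steps: int = 800,
    seed: int | None = None,
    **kwargs,
) -> AdaptationRecord:
    """Single-robot convenience wrapper around :func:`adapt`."""
    return adapt(
        arena, [config], task, mechanism, epochs, steps, seed, **kwargs
    )[0]
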