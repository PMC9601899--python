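"""Experiment orchestration: configs, seeding, logging and fixtures.

Binds arena, controllers, adaptation and analysis into the full design --
tasks x mechanisms x generation biases, several independent runs of a
10-robot population each.  ``full_profile`` mirrors the full-scale study
(n=1000, 500 epochs, 50 runs); ``desk_profile`` is a scaled configuration
(n=200, 2 robots, 30 epochs, 2 runs) suitable for quick checks and the
test suite.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptation import adapt, canonical_mechanism, make_robot_config
from .arena import Arena, DEFAULT_PHYSICS, arena_task1, arena_task2, arena_task3
from .derrida import derrida_trajectory
from .objectives import EpochTrace
from .rbn import BooleanNetwork, EnsembleSpec

__all__ = [
    "ExperimentConfig",
    "full_profile",
    "desk_profile",
    "arena_for_task",
    "run_experiment",
    "make_fixtures",
]

log = logging.getLogger("bnbot")

_ARENAS = {1: arena_task1, 2: arena_task2, 3: arena_task3}


def arena_for_task(task: int, overrides: dict | None = None) -> Arena:
    return _ARENAS[task](**(overrides or {}))


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one experimental sweep.

    Defaults mirror the study design: k=3, dt=0.1 s, 80 s epochs (800
    steps at 10 steps/s), populations of 10 robots, 500 epochs, 50 runs
    per parameter combination, biases {0.1, 0.21, 0.5, 0.79, 0.9}.
    """

    task: int = 1
    mechanism: str = "in-out-mapping"
    p_values: tuple[float, ...] = (0.1, 0.21, 0.5, 0.79, 0.9)
    n: int = 1000
    k: int = 3
    epochs: int = 500
    steps_per_epoch: int = 800
    robots: int = 10
    runs: int = 50
    seed: int = 0
    arena_overrides: dict = field(default_factory=dict)
    compute_derrida: bool = False
    derrida_n_pert: int | None = None
    save_checkpoints: bool = False
    save_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.task not in (1, 2, 3):
            raise ValueError(f"unknown task {self.task}")
        canonical_mechanism(self.mechanism)


def full_profile(**overrides) -> ExperimentConfig:
    """Full-scale configuration."""
    return dataclasses.replace(ExperimentConfig(), **overrides)


def desk_profile(**overrides) -> ExperimentConfig:
    """Scaled configuration for quick checks (n=200, 2 robots, 30 epochs,
    2 runs, the three regime-defining biases)."""
    base = ExperimentConfig(
        p_values=(0.1, 0.21, 0.5), n=200, epochs=30, robots=2, runs=2
    )
    return dataclasses.replace(base, **overrides)


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Run the sweep; optionally write CSV/JSON artifacts under
    ``out_dir``.

    Deterministic given ``config.seed``: one child seed stream per
    (bias, run) pair.  Returns the long-format per-epoch score table with
    columns (run, robot, epoch, mechanism, p, task, score, accepted) and,
    if requested, writes scores.csv, derrida.csv, manifest.json,
    checkpoints and best-epoch state trajectories.
    """
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    arena = arena_for_task(config.task, config.arena_overrides)
    root_ss = np.random.SeedSequence(config.seed)
    children = root_ss.spawn(len(config.p_values) * config.runs)
    rows = []
    derrida_rows = []
    need_states = config.compute_derrida or config.save_trajectories
    for pi, p in enumerate(config.p_values):
        spec = EnsembleSpec(n=config.n, k=config.k, p=p)
        for run in range(config.runs):
            ss = children[pi * config.runs + run]
            gen_ss, adapt_ss = ss.spawn(2)
            gen_rng = np.random.default_rng(gen_ss)
            configs = [
                make_robot_config(spec, config.task, gen_rng)
                for _ in range(config.robots)
            ]
            log.info(
                "task %d mech %s p=%.2f run %d", config.task, config.mechanism,
                p, run,
            )
            records = adapt(
                arena,
                configs,
                config.task,
                config.mechanism,
                epochs=config.epochs,
                steps=config.steps_per_epoch,
                seed=adapt_ss,
                record_states=need_states,
            )
            for ri, rec in enumerate(records):
                for e in range(config.epochs):
                    rows.append(
                        (run, ri, e, config.mechanism, p, config.task,
                         rec.scores[e], bool(rec.accepted[e]))
                    )
                if config.compute_derrida:
                    dres = derrida_trajectory(
                        rec.final_config.network,
                        rec.best_states,
                        config.derrida_n_pert,
                        np.random.default_rng(ss.spawn(1)[0]),
                    )
                    derrida_rows.append(
                        (run, ri, config.mechanism, p, config.task,
                         rec.best_score, dres.mean_lambda, dres.regime)
                    )
                if out is not None and config.save_checkpoints:
                    ck = out / f"checkpoint_p{p}_run{run}_robot{ri}.json"
                    ck.write_text(json.dumps({
                        "network": json.loads(rec.final_config.network.to_json()),
                        "coupling": rec.final_config.coupling.to_dict(),
                        "best_epoch": rec.best_epoch,
                        "best_score": rec.best_score,
                    }))
                if out is not None and config.save_trajectories:
                    tf = out / f"best_states_p{p}_run{run}_robot{ri}.txt"
                    np.savetxt(tf, rec.best_states, fmt="%d")
    scores = pd.DataFrame(
        rows,
        columns=["run", "robot", "epoch", "mechanism", "p", "task", "score",
                 "accepted"],
    )
    if out is not None:
        scores.to_csv(out / "scores.csv", index=False)
        manifest = {
            "config": {
                **{k: v for k, v in dataclasses.asdict(config).items()},
                "p_values": list(config.p_values),
            },
            "arena": arena.to_dict(),
            "physics": dataclasses.asdict(DEFAULT_PHYSICS),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if config.compute_derrida:
        dd = pd.DataFrame(
            derrida_rows,
            columns=["run", "robot", "mechanism", "p", "task", "best_score",
                     "mean_lambda", "regime"],
        )
        if out is not None:
            dd.to_csv(out / "derrida.csv", index=False)
        scores.attrs["derrida"] = dd
    return scores


def trajectory_frame(trace: EpochTrace, epoch: int, robot: int) -> pd.DataFrame:
    """One CSV row per step for a recorded trace (trajectory writer)."""
    E = len(trace)
    return pd.DataFrame({
        "epoch": epoch,
        "step": np.arange(E),
        "theta": trace.theta,
        "l": trace.left,
        "r": trace.right,
        "region": trace.region if trace.region else [""] * E,
        "action": trace.action if trace.action else ["none"] * E,
        "robot": robot,
    })


def make_fixtures(seed: int = 0) -> dict:
    """Tiny deterministic instances used by the test suite.

    Includes a constant (all-zero-table) network whose one-step divergence
    is 0, a copy network (each node copies its first source, wiring a
    cyclic shift) with divergence exactly 1, a small random network, a
    4-step navigation trace whose hand-computed score is 37.5, and the
    default navigation arena.
    """
    rng = np.random.default_rng(seed)
    n, k = 12, 3

    def small_wiring() -> np.ndarray:
        w = np.empty((n, k), dtype=np.int64)
        for i in range(n):
            cands = np.delete(np.arange(n), i)
            w[i] = rng.choice(cands, size=k, replace=False)
        return w

    constant = BooleanNetwork(
        small_wiring(), np.zeros((n, 2**k), dtype=np.uint8),
        rng.integers(0, 2, n, dtype=np.uint8),
    )
    # each node copies its first source; first source = (i+1) mod n
    copy_wiring = small_wiring()
    copy_wiring[:, 0] = (np.arange(n) + 1) % n
    for i in range(n):  # keep rows distinct after forcing column 0
        while len(set(copy_wiring[i])) < k:
            cands = np.delete(np.arange(n), [i, copy_wiring[i, 0]])
            copy_wiring[i, 1:] = rng.choice(cands, size=k - 1, replace=False)
    # big-endian: MSB (first source) decides -> rows 0..3 -> 0, 4..7 -> 1
    copy_tables = np.tile(
        np.concatenate([np.zeros(2 ** (k - 1), np.uint8),
                        np.ones(2 ** (k - 1), np.uint8)]), (n, 1)
    )
    copy_net = BooleanNetwork(
        copy_wiring, copy_tables, rng.integers(0, 2, n, dtype=np.uint8)
    )
    random_net = BooleanNetwork(
        small_wiring(),
        rng.integers(0, 2, (n, 2**k), dtype=np.uint8),
        rng.integers(0, 2, n, dtype=np.uint8),
        p=0.5,
    )
    task1_trace = EpochTrace(
        theta=np.array([0.0, 0.5, 0.0, 0.0]),
        left=np.array([1.0, 1.0, 1.0, 0.0]),
        right=np.array([1.0, 1.0, 0.0, 0.0]),
    )  # (100/4) * (1 + 0.5 + 0 + 0) = 37.5
    return {
        "constant_net": constant,
        "copy_net": copy_net,
        "random_net": random_net,
        "task1_trace": task1_trace,
        "arena": arena_task1(),
    }
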