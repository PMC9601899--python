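"""Task objective functions.

All three objectives accumulate a per-step term over an epoch of E control
steps and scale by 100/E.

* Navigation: ``(1 - theta) (1 - |l - r|) (l + r) / 2`` rewards straight,
  fast, collision-free motion (theta is the maximum normalized proximity
  reading).
* Region-bound navigation: the same term multiplied by eps = +1 in the
  robot's assigned region and -1 otherwise.
* Foraging: ``rho + (1 - 2 theta) (1 - |l - r|) (l + r) / 2`` where rho is
  an event reward (+50 for a pick-up in the blue zone or a deposit of a
  carried object in the green zone, -100 for a deposit of a carried object
  anywhere else) and the doubled theta further penalizes collisions.  The
  reward symbol is named rho here to avoid the clash with the right wheel
  speed r.

The virtual hook is edge-triggered: a 0->1 transition of the hook output
attempts a pick-up, a 1->0 transition attempts a deposit; a level-held
hook performs no action, and its closed position is the robot's only
memory of carrying an object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EpochTrace",
    "score_task1",
    "score_task2",
    "score_task3",
    "reward_rule",
    "hook_action",
    "score",
]

REWARD_PICKUP = 50.0
REWARD_DEPOSIT = 50.0
PENALTY_BAD_DEPOSIT = -100.0


@dataclass
class EpochTrace:
    """Per-step record of one robot over one epoch.

    theta, left, right are length-E float arrays; eps_region (+-1) is used
    by the region task; reward and action by the foraging task.
    """

    theta: np.ndarray
    left: np.ndarray
    right: np.ndarray
    eps_region: np.ndarray | None = None
    reward: np.ndarray | None = None
    action: list | None = None
    region: list | None = None

    def __len__(self) -> int:
        return len(self.theta)


def _movement(trace: EpochTrace) -> np.ndarray:
    l, r = trace.left, trace.right
    return (1.0 - np.abs(l - r)) * (l + r) / 2.0


def score_task1(trace: EpochTrace) -> float:
    """Navigation score, in [0, 100]."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    return float(100.0 / len(trace) * ((1.0 - trace.theta) * _movement(trace)).sum())


def score_task2(trace: EpochTrace) -> float:
    """Region-bound navigation score, in [-100, 100]."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    if trace.eps_region is None:
        raise ValueError("trace lacks region information")
    per_step = trace.eps_region * (1.0 - trace.theta) * _movement(trace)
    return float(100.0 / len(trace) * per_step.sum())


def score_task3(trace: EpochTrace) -> float:
    """Foraging score: event rewards plus the doubled-collision-penalty
    movement term (may be negative)."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    rho = trace.reward if trace.reward is not None else 0.0
    per_step = rho + (1.0 - 2.0 * trace.theta) * _movement(trace)
    return float(100.0 / len(trace) * np.sum(per_step))


_SCORERS = {1: score_task1, 2: score_task2, 3: score_task3}


def score(task: int, trace: EpochTrace) -> float:
    """Dispatch to the task's objective."""
    return _SCORERS[task](trace)


def hook_action(prev_hook: bool, hook: bool) -> str:
    """Edge-triggered hook semantics: 0->1 pick up, 1->0 deposit."""
    if hook and not prev_hook:
        return "pickup"
    if prev_hook and not hook:
        return "deposit"
    return "none"


def reward_rule(action: str, region: str, carrying: bool) -> tuple[float, bool]:
    """Foraging reward and new carrying flag.

    Pick-up is valid only in the blue zone while not carrying (+50);
    deposit is possible only while carrying: +50 in the green zone, -100
    elsewhere.  Invalid actions yield 0 and leave the carrying flag
    unchanged.
    """
    if action == "pickup":
        if region == "blue" and not carrying:
            return REWARD_PICKUP, True
        return 0.0, carrying
    if action == "deposit":
        if not carrying:
            return 0.0, False
        if region == "green":
            return REWARD_DEPOSIT, False
        return PENALTY_BAD_DEPOSIT, False
    if action != "none":
        raise ValueError(f"unknown action {action!r}")
    return 0.0, carrying
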