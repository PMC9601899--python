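"""One-step Derrida divergence and dynamical-regime classification.

The Derrida value of a state is the mean Hamming distance, after one
synchronous update, between the state and copies with a single node
negated.  Averaged over states it estimates the perturbation-spreading
rate of the network: below 1 the dynamics are ordered, near 1 critical,
above 1 chaotic.  For networks embedded in robots the measurement can be
restricted to the states actually visited during the robot's best epoch,
yielding the *actual* (as opposed to nominal) operating regime.

The annealed mean-field approximation predicts lambda = 2 p (1 - p) k for
a fresh ensemble with bias p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rbn import BooleanNetwork, EnsembleSpec, generate_rbn, step_states

__all__ = [
    "DerridaResult",
    "derrida_state",
    "derrida_states",
    "derrida_trajectory",
    "classify_regime",
    "annealed_lambda",
    "ensemble_derrida",
]

#: Default number of single-node flips per state ("all the possible
#: perturbations, n=100"); all nodes are used when the network is smaller.
DEFAULT_PERTURBATIONS = 100


def classify_regime(D: float, eps: float = 0.3) -> str:
    """Classify a Derrida value: ordered if D < 1-eps, critical if
    1-eps <= D <= 1+eps, chaotic if D > 1+eps."""
    if D < 0:
        raise ValueError(f"Derrida value must be >= 0, got {D}")
    if D < 1.0 - eps:
        return "ordered"
    if D <= 1.0 + eps:
        return "critical"
    return "chaotic"


def annealed_lambda(p: float, k: int) -> float:
    """Annealed-approximation expected one-step divergence 2 p (1-p) k."""
    return 2.0 * p * (1.0 - p) * k


def _resolve_n_pert(n: int, n_pert: int | None) -> int:
    if n_pert is None:
        n_pert = min(DEFAULT_PERTURBATIONS, n)
    if n_pert > n:
        raise ValueError(f"n_pert={n_pert} exceeds node count {n}")
    if n_pert < 1:
        raise ValueError("n_pert must be >= 1")
    return n_pert


def derrida_state(
    net: BooleanNetwork,
    state: np.ndarray,
    n_pert: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean one-step divergence of ``state`` over ``n_pert`` distinct
    single-node flips.

    A copy of the state is made, one randomly chosen node is negated, both
    states are updated synchronously and the Hamming distance of the
    results is recorded; the average over flips is returned.
    """
    return derrida_states(net, np.atleast_2d(state), n_pert, rng)[0]


def derrida_states(
    net: BooleanNetwork,
    states: np.ndarray,
    n_pert: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized :func:`derrida_state` over a (S, n) batch of states."""
    states = np.asarray(states, dtype=np.uint8)
    S, n = states.shape
    n_pert = _resolve_n_pert(n, n_pert)
    if rng is None:
        rng = np.random.default_rng()
    base_next = step_states(net, states)  # (S, n)
    out = np.empty(S)
    for s in range(S):
        # fresh draw of distinct perturbation nodes for every state
        flips = rng.choice(n, size=n_pert, replace=False)
        pert = np.repeat(states[s][None, :], n_pert, axis=0)
        pert[np.arange(n_pert), flips] ^= 1
        pert_next = step_states(net, pert)
        out[s] = np.count_nonzero(pert_next != base_next[s][None, :], axis=1).mean()
    return out


@dataclass
class DerridaResult:
    """Per-state and mean one-step divergence with the implied regime."""

    per_state_lambda: np.ndarray
    mean_lambda: float
    n_perturbations: int
    regime: str


def derrida_trajectory(
    net: BooleanNetwork,
    states: np.ndarray,
    n_pert: int | None = None,
    rng: np.random.Generator | None = None,
    eps: float = 0.3,
) -> DerridaResult:
    """Trajectory-restricted Derrida value: the mean over all visited
    states (e.g. the 800 states of a robot's best epoch) of the per-state
    one-step divergence.

    The measurement concerns the isolated network: no sensor overwriting
    is applied while perturbing and updating.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.uint8))
    if states.shape[0] == 0:
        raise ValueError("empty trajectory")
    n_pert = _resolve_n_pert(states.shape[1], n_pert)
    per_state = derrida_states(net, states, n_pert, rng)
    mean = float(per_state.mean())
    return DerridaResult(per_state, mean, n_pert, classify_regime(mean, eps))


def ensemble_derrida(
    spec: EnsembleSpec,
    n_nets: int = 50,
    n_states: int = 50,
    n_pert: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean Derrida value of ``n_nets`` fresh networks from ``spec``, each
    measured on ``n_states`` uniform random states.  Returns the per-network
    means."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    means = np.empty(n_nets)
    for i in range(n_nets):
        net = generate_rbn(spec, rng=rng)
        states = rng.integers(0, 2, size=(n_states, spec.n), dtype=np.uint8)
        means[i] = derrida_states(net, states, n_pert, rng).mean()
    return means
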