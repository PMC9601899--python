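"""Mutation-only drift of the dynamical regime (null model).

Repeatedly applying the structural mutation operator (negate 1% of the
truth-table bits, redistribute 1% of the arcs) with no selection drives
the truth-table bias b toward 0.5: every flipped bit is resampled to the
opposite value, so the expected bias relaxes as

    b_t = 0.5 + (b_0 - 0.5) (1 - 2 q)^t,     q = fraction of bits flipped

and, by the annealed approximation, the expected one-step divergence is
lambda_t = 2 b_t (1 - b_t) k.  Rewiring preserves the bias and is taken as
neutral in the analytic law.  An ensemble initialized in the ordered
regime (b_0 = 0.1, k = 3) therefore crosses into the chaotic band
(lambda > 1.3) within a few tens of epochs -- without any adaptive
pressure.  The module provides both the Monte-Carlo simulation and the
closed form; their agreement is the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .derrida import classify_regime, derrida_states
from .rbn import BooleanNetwork, EnsembleSpec, generate_rbn, truth_table_bias
from .adaptation import mutate

__all__ = [
    "DriftTrajectory",
    "simulate_drift",
    "bias_closed_form",
    "lambda_closed_form",
]


def bias_closed_form(b0: float, q: float, t: int | np.ndarray) -> float | np.ndarray:
    """Expected truth-table bias after t epochs of flipping a fraction q of
    the bits per epoch: 0.5 + (b0 - 0.5)(1 - 2q)^t."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    return 0.5 + (b0 - 0.5) * (1.0 - 2.0 * q) ** np.asarray(t, dtype=float)


def lambda_closed_form(
    b0: float, q: float, t: int | np.ndarray, k: int = 3
) -> float | np.ndarray:
    """Companion expected Derrida value 2 b_t (1 - b_t) k."""
    b = bias_closed_form(b0, q, t)
    return 2.0 * b * (1.0 - b) * k


@dataclass
class DriftTrajectory:
    """Ensemble drift record; row 0 is the unmutated (nominal) ensemble."""

    mean_bias: np.ndarray  # (epochs+1,)
    lambda_per_net: np.ndarray  # (epochs+1, ensemble)
    mean_lambda: np.ndarray  # (epochs+1,)
    frac_chaotic: np.ndarray  # (epochs+1,)
    first_all_chaotic: int | None  # first epoch with every network chaotic


def simulate_drift(
    spec: EnsembleSpec,
    epochs: int,
    ensemble_size: int = 20,
    rng: np.random.Generator | None = None,
    n_states: int = 20,
    n_pert: int | None = None,
    eps: float = 0.3,
    stop_when_all_chaotic: bool = False,
) -> DriftTrajectory:
    """Apply the mutation operator to every network each epoch, with no
    selection, and track the ensemble's bias and Derrida value.

    Each network's Derrida value is estimated every epoch on ``n_states``
    fresh uniform random states with ``n_pert`` single-node flips per
    state.  With ``stop_when_all_chaotic`` the simulation ends at the
    first epoch where every network classifies chaotic (remaining rows are
    trimmed).
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    nets = [generate_rbn(spec, rng=rng) for _ in range(ensemble_size)]

    def measure(nets: list[BooleanNetwork]) -> tuple[float, np.ndarray]:
        lams = np.empty(len(nets))
        for i, net in enumerate(nets):
            states = rng.integers(0, 2, size=(n_states, spec.n), dtype=np.uint8)
            lams[i] = derrida_states(net, states, n_pert, rng).mean()
        bias = float(np.mean([truth_table_bias(net) for net in nets]))
        return bias, lams

    mean_bias: list[float] = []
    lam_rows = []
    frac = []
    first_all = None
    b, lams = measure(nets)
    mean_bias.append(b)
    lam_rows.append(lams)
    frac.append(np.mean([classify_regime(l, eps) == "chaotic" for l in lams]))
    for t in range(1, epochs + 1):
        nets = [mutate(net, rng) for net in nets]
        b, lams = measure(nets)
        mean_bias.append(b)
        lam_rows.append(lams)
        fc = float(np.mean([classify_regime(l, eps) == "chaotic" for l in lams]))
        frac.append(fc)
        if fc == 1.0 and first_all is None:
            first_all = t
            if stop_when_all_chaotic:
                break
    lam = np.array(lam_rows)
    return DriftTrajectory(
        np.array(mean_bias),
        lam,
        lam.mean(axis=1),
        np.array(frac),
        first_all,
    )
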