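"""Summary statistics over adaptation runs.

Four statistics characterize a (task, mechanism, bias) case:

* the per-epoch *mean of max* curve: each robot's cumulative-best score,
  averaged over robots (always non-decreasing);
* the *area under* that curve (unit-step summation over epochs), ranked
  from highest to lowest across cases;
* box statistics of the per-robot maximum scores;
* the *mean rank of max scores*: all robots' max scores are ranked
  globally (descending, ties averaged) and the ranks averaged per
  (mechanism x regime) group -- the lower the better.  The grouping regime
  can be *nominal* (from the generation bias) or *actual* (from the
  trajectory-restricted Derrida value of the best epoch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .derrida import classify_regime
from .rbn import nominal_regime

__all__ = [
    "RegimeAssignment",
    "regime_assignment",
    "mean_of_max_curve",
    "auc",
    "rank_by_auc",
    "max_scores",
    "mean_rank_of_max",
    "box_stats",
    "rank_sum_test",
    "plot_mean_of_max",
]


@dataclass(frozen=True)
class RegimeAssignment:
    """Nominal (generation-bias) vs actual (measured Derrida) regime."""

    nominal: str
    actual: str


def regime_assignment(p: float, mean_lambda: float, eps: float = 0.3) -> RegimeAssignment:
    return RegimeAssignment(nominal_regime(p), classify_regime(mean_lambda, eps))


def mean_of_max_curve(scores: np.ndarray) -> np.ndarray:
    """Per-epoch mean over robots of the cumulative-best score.

    ``scores`` has shape (robots, epochs); the result is non-decreasing.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.size == 0:
        raise ValueError("empty score matrix")
    return np.maximum.accumulate(scores, axis=1).mean(axis=0)


def auc(curve: np.ndarray) -> float:
    """Area under a per-epoch curve by unit-step summation."""
    return float(np.sum(curve))


def rank_by_auc(cases: dict[str, np.ndarray]) -> pd.DataFrame:
    """Rank case labels by the area under their mean-of-max curves,
    highest first; ties broken lexicographically by label."""
    rows = sorted(
        ((label, auc(curve)) for label, curve in cases.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return pd.DataFrame(
        {"rank": np.arange(1, len(rows) + 1),
         "case": [r[0] for r in rows],
         "auc": [r[1] for r in rows]}
    )


def max_scores(scores: np.ndarray) -> np.ndarray:
    """Per-robot maximum score over all epochs."""
    return np.atleast_2d(np.asarray(scores, float)).max(axis=1)


def mean_rank_of_max(
    df: pd.DataFrame,
    score_col: str = "max_score",
    group_cols: tuple[str, str] = ("mechanism", "regime"),
) -> pd.DataFrame:
    """Global descending rank of all max scores (average rank on ties),
    averaged per group.  Lower is better."""
    ranks = df[score_col].rank(ascending=False, method="average")
    out = (
        df.assign(rank=ranks)
        .groupby(list(group_cols), observed=True)["rank"]
        .mean()
        .reset_index()
        .rename(columns={"rank": "mean_rank"})
        .sort_values("mean_rank", ignore_index=True)
    )
    return out


def box_stats(values: np.ndarray) -> dict[str, float]:
    """Quartiles and Tukey whiskers of a sample (for box-plot export)."""
    v = np.asarray(values, float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
        "n_outliers": int(((v < lo) | (v > hi)).sum()),
    }


def rank_sum_test(a: np.ndarray, b: np.ndarray):
    """Unpaired two-sample Wilcoxon rank-sum test (off-the-shelf)."""
    from scipy import stats

    return stats.ranksums(a, b)


def plot_mean_of_max(cases: dict[str, np.ndarray], ax=None, title: str = ""):
    """Plot mean-of-max curves per case (thin optional layer)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in cases.items():
        ax.plot(np.arange(len(curve)), curve, label=label)
    ax.set_xlabel("epoch")
    ax.set_ylabel("mean of max score")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
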