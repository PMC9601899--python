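"""Random Boolean networks (RBNs) with uniform in-degree.

An RBN has ``n`` nodes, each updated synchronously by a Boolean function of
``k`` randomly chosen source nodes (no self-loops).  Truth-table entries are
drawn i.i.d. Bernoulli(``p``); the bias ``p`` places the ensemble in the
ordered (p in {0.1, 0.9}), critical (p in {0.21, 0.79}) or chaotic (p = 0.5)
dynamical regime for k = 3.  Nodes wired to robot actuators are always given
bias-0.5 functions so high/low biases do not trivially freeze the wheels.

Truth-table rows are indexed big-endian: the first source is the most
significant bit of the row index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnsembleSpec",
    "BooleanNetwork",
    "generate_rbn",
    "synchronous_step",
    "step_states",
    "hamming",
    "nominal_regime",
    "truth_table_bias",
]

#: Dynamical regime implied by the generation bias, for k = 3.
REGIME_BY_BIAS = {
    0.1: "ordered",
    0.9: "ordered",
    0.21: "critical",
    0.79: "critical",
    0.5: "chaotic",
}


def nominal_regime(p: float) -> str:
    """Regime label implied by the generation bias ``p`` (k = 3 ensembles)."""
    try:
        return REGIME_BY_BIAS[round(float(p), 2)]
    except KeyError:
        raise ValueError(f"no nominal regime defined for bias p={p!r}") from None


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of an RBN ensemble: node count, in-degree, bias, seed."""

    n: int = 1000
    k: int = 3
    p: float = 0.5
    output_bias: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k >= self.n:
            raise ValueError(f"k={self.k} must be < n={self.n} (no self loops)")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"bias p={self.p} outside (0, 1]")

    @property
    def nominal_regime(self) -> str:
        return nominal_regime(self.p)


@dataclass
class BooleanNetwork:
    """A synchronously-updated Boolean network with uniform in-degree k.

    Attributes
    ----------
    wiring : (n, k) int array
        Source node indices per node; distinct per row, never the node itself.
    truth_tables : (n, 2**k) uint8 array
        One row of 2**k Boolean entries per node.
    state : (n,) uint8 array
        Current Boolean state.
    p : float or None
        Generation bias, kept as provenance metadata.
    """

    wiring: np.ndarray
    truth_tables: np.ndarray
    state: np.ndarray
    p: float | None = None
    _weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.wiring = np.ascontiguousarray(self.wiring, dtype=np.int64)
        self.truth_tables = np.ascontiguousarray(self.truth_tables, dtype=np.uint8)
        self.state = np.ascontiguousarray(self.state, dtype=np.uint8)
        n, k = self.wiring.shape
        if self.truth_tables.shape != (n, 2**k):
            raise ValueError(
                f"truth_tables shape {self.truth_tables.shape} != ({n}, {2 ** k})"
            )
        if self.state.shape != (n,):
            raise ValueError(f"state length {self.state.shape} != ({n},)")
        if (self.wiring < 0).any() or (self.wiring >= n).any():
            raise ValueError("wiring index out of range")
        if (self.wiring == np.arange(n)[:, None]).any():
            raise ValueError("self loops are not allowed")
        if any(len(set(row)) != k for row in self.wiring):
            raise ValueError("duplicate sources within a node")
        # big-endian row index: first source is the most significant bit
        self._weights = (2 ** np.arange(k - 1, -1, -1)).astype(np.int64)

    @property
    def n(self) -> int:
        return self.wiring.shape[0]

    @property
    def k(self) -> int:
        return self.wiring.shape[1]

    def copy(self) -> "BooleanNetwork":
        return BooleanNetwork(
            self.wiring.copy(), self.truth_tables.copy(), self.state.copy(), self.p
        )

    # -- serialization ----------------------------------------------------

    def to_text(self) -> str:
        """Line-oriented text form: header ``n k p``, one node per line
        (sources, then the 2**k truth-table bits as a 0/1 string)."""
        lines = [f"{self.n} {self.k} {'' if self.p is None else self.p}".rstrip()]
        for srcs, row in zip(self.wiring, self.truth_tables):
            bits = "".join(map(str, row.tolist()))
            lines.append(" ".join(map(str, srcs.tolist())) + " " + bits)
        lines.append("state " + "".join(map(str, self.state.tolist())))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "BooleanNetwork":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        head = lines[0].split()
        n, k = int(head[0]), int(head[1])
        p = float(head[2]) if len(head) > 2 else None
        wiring = np.empty((n, k), dtype=np.int64)
        tables = np.empty((n, 2**k), dtype=np.uint8)
        for i, ln in enumerate(lines[1 : n + 1]):
            parts = ln.split()
            wiring[i] = [int(s) for s in parts[:k]]
            tables[i] = [int(c) for c in parts[k]]
        state_line = lines[n + 1].split()
        state = np.array([int(c) for c in state_line[1]], dtype=np.uint8)
        return cls(wiring, tables, state, p)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "k": self.k,
                "p": self.p,
                "wiring": self.wiring.tolist(),
                "truth_tables": self.truth_tables.tolist(),
                "state": self.state.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BooleanNetwork":
        d = json.loads(text)
        return cls(
            np.array(d["wiring"]),
            np.array(d["truth_tables"]),
            np.array(d["state"]),
            d.get("p"),
        )


def generate_rbn(
    spec: EnsembleSpec,
    output_nodes: tuple[int, ...] = (),
    rng: np.random.Generator | None = None,
) -> BooleanNetwork:
    """Sample an RBN from the ensemble defined by ``spec``.

    Each node receives ``k`` distinct sources drawn uniformly from the other
    ``n - 1`` nodes; each truth-table entry is 1 with probability ``p``,
    except for ``output_nodes`` (actuator-controlling nodes), whose tables
    use ``spec.output_bias`` (0.5 by default).  The initial state is uniform
    random.  Deterministic under ``spec.seed`` / ``rng``.
    """
    n, k, p = spec.n, spec.k, spec.p
    output_nodes = tuple(output_nodes)
    if any(o < 0 or o >= n for o in output_nodes):
        raise ValueError("output node index out of range")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    # k smallest of n iid uniforms (self excluded) = uniform k-subset of others
    scores = rng.random((n, n))
    np.fill_diagonal(scores, np.inf)
    wiring = np.argpartition(scores, k, axis=1)[:, :k].astype(np.int64)
    tables = (rng.random((n, 2**k)) < p).astype(np.uint8)
    if output_nodes:
        idx = np.array(output_nodes, dtype=np.int64)
        tables[idx] = (rng.random((len(idx), 2**k)) < spec.output_bias).astype(
            np.uint8
        )
    state = rng.integers(0, 2, size=n, dtype=np.uint8)
    return BooleanNetwork(wiring, tables, state, p=p)


def synchronous_step(net: BooleanNetwork, state: np.ndarray | None = None) -> np.ndarray:
    """One synchronous update: every node simultaneously takes the
    truth-table entry indexed by its sources' current values.

    Pure function of the input state (``net.state`` by default); the network
    is not modified.
    """
    if state is None:
        state = net.state
    state = np.asarray(state, dtype=np.uint8)
    if state.shape != (net.n,):
        raise ValueError(f"state length {state.shape} != ({net.n},)")
    idx = state[net.wiring] @ net._weights
    return net.truth_tables[np.arange(net.n), idx]


def step_states(net: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Synchronous update of a batch of states, shape (m, n) -> (m, n)."""
    states = np.asarray(states, dtype=np.uint8)
    idx = states[:, net.wiring] @ net._weights
    return net.truth_tables[np.arange(net.n)[None, :], idx]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of positions at which two Boolean states differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def truth_table_bias(net: BooleanNetwork) -> float:
    """Fraction of 1s over all truth-table entries."""
    return float(net.truth_tables.mean())
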