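"""Sensor/actuator <-> network-node coupling.

Sensor readings are encoded into Boolean values that overwrite designated
*input nodes* before each synchronous update; after the update the values
of the *output nodes* drive the actuators (wheel bit 1 -> full speed, 0 ->
stop; third bit, when present, the virtual hook).

Channel layouts per task:

===========  ======================================  ========
task         input channels                          outputs
===========  ======================================  ========
1 navigate   8 proximity                             2 wheels
2 regions    8 proximity + 1 region feedback         2 wheels
3 foraging   8 proximity + 8 light + 2 region code   2 wheels + hook
===========  ======================================  ========

The 24 raw proximity (and light) readings are aggregated into consecutive
groups of 3 by maximum and thresholded at 0.1 (strictly greater-than).
The region code of the foraging task is 00 neutral, 01 green, 10 blue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Coupling",
    "TASK_INPUT_COUNTS",
    "TASK_OUTPUT_COUNTS",
    "build_coupling",
    "encode_proximity",
    "encode_light",
    "encode_region",
    "encode_inputs",
    "apply_inputs",
    "read_outputs",
    "remap",
]

TASK_INPUT_COUNTS = {1: 8, 2: 9, 3: 18}
TASK_OUTPUT_COUNTS = {1: 2, 2: 2, 3: 3}

#: Boolean threshold on the per-group maximum sensor reading.
SENSOR_THRESHOLD = 0.1


@dataclass(frozen=True)
class Coupling:
    """Ordered node assignments: one node per Boolean input channel and one
    per actuator channel; all indices distinct, input and output disjoint."""

    input_nodes: tuple[int, ...]
    output_nodes: tuple[int, ...]

    def __post_init__(self) -> None:
        all_nodes = self.input_nodes + self.output_nodes
        if len(set(all_nodes)) != len(all_nodes):
            raise ValueError("coupling node indices must be distinct and disjoint")

    @property
    def used_nodes(self) -> frozenset[int]:
        return frozenset(self.input_nodes) | frozenset(self.output_nodes)

    def to_dict(self) -> dict:
        return {
            "input_nodes": list(self.input_nodes),
            "output_nodes": list(self.output_nodes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Coupling":
        return cls(tuple(d["input_nodes"]), tuple(d["output_nodes"]))


def build_coupling(task: int, n: int, rng: np.random.Generator) -> Coupling:
    """Sample a random coupling with the channel counts of ``task``."""
    n_in = TASK_INPUT_COUNTS[task]
    n_out = TASK_OUTPUT_COUNTS[task]
    if n <= n_in + n_out:
        raise ValueError(f"n={n} too small for {n_in + n_out} channels")
    nodes = rng.choice(n, size=n_in + n_out, replace=False)
    return Coupling(tuple(int(v) for v in nodes[:n_in]),
                    tuple(int(v) for v in nodes[n_in:]))


def _group_max_threshold(readings: np.ndarray, threshold: float) -> np.ndarray:
    readings = np.asarray(readings, float)
    if readings.shape != (24,):
        raise ValueError(f"expected 24 readings, got shape {readings.shape}")
    grouped = readings.reshape(8, 3).max(axis=1)
    return (grouped > threshold).astype(np.uint8)


def encode_proximity(
    readings: np.ndarray, threshold: float = SENSOR_THRESHOLD
) -> np.ndarray:
    """24 proximity readings -> 8 Booleans: consecutive groups of 3,
    per-group maximum, 1 iff strictly greater than the threshold."""
    return _group_max_threshold(readings, threshold)


def encode_light(
    readings: np.ndarray, threshold: float = SENSOR_THRESHOLD
) -> np.ndarray:
    """24 light readings -> 8 Booleans (same grouping scheme as proximity)."""
    return _group_max_threshold(readings, threshold)


def encode_region(
    task: int, region: str, assigned: str | None = None
) -> tuple[int, ...]:
    """Region feedback bits.

    Task 2: a single bit, 1 iff the robot is in its assigned region.
    Task 3: the printed two-bit code (neutral 00, green 01, blue 10).
    """
    if task == 2:
        if region not in ("left", "right"):
            raise ValueError(f"unknown region {region!r} for task 2")
        return (int(region == assigned),)
    if task == 3:
        codes = {"neutral": (0, 0), "green": (0, 1), "blue": (1, 0)}
        try:
            return codes[region]
        except KeyError:
            raise ValueError(f"unknown region {region!r} for task 3") from None
    raise ValueError(f"task {task} has no region channel")


def encode_inputs(
    task: int,
    prox: np.ndarray,
    light: np.ndarray | None = None,
    region: str | None = None,
    assigned: str | None = None,
) -> np.ndarray:
    """Concatenate the task's Boolean input channels in layout order."""
    bits = [encode_proximity(prox)]
    if task == 2:
        bits.append(np.asarray(encode_region(2, region, assigned), dtype=np.uint8))
    elif task == 3:
        bits.append(encode_light(light))
        bits.append(np.asarray(encode_region(3, region), dtype=np.uint8))
    out = np.concatenate(bits)
    assert out.shape == (TASK_INPUT_COUNTS[task],)
    return out


def apply_inputs(
    state: np.ndarray, coupling: Coupling, bits: np.ndarray
) -> np.ndarray:
    """Overwrite the input nodes with the encoded sensor bits (done before
    each synchronous update).  Returns a new state array."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.shape != (len(coupling.input_nodes),):
        raise ValueError(
            f"expected {len(coupling.input_nodes)} bits, got {bits.shape}"
        )
    out = np.array(state, dtype=np.uint8, copy=True)
    out[list(coupling.input_nodes)] = bits
    return out


def read_outputs(state: np.ndarray, coupling: Coupling) -> np.ndarray:
    """Values of the output nodes (read after the synchronous update)."""
    return np.asarray(state, dtype=np.uint8)[list(coupling.output_nodes)]


def remap(
    coupling: Coupling,
    n: int,
    rng: np.random.Generator,
    n_inputs: int = 2,
    n_outputs: int = 1,
) -> Coupling:
    """In-out mapping move: reassign ``n_inputs`` input channels and
    ``n_outputs`` output channels to nodes not currently used by any
    channel, chosen uniformly.  All other assignments -- and the network
    itself -- are untouched."""
    used = coupling.used_nodes
    if n <= len(used) + n_inputs + n_outputs:
        raise ValueError("network too small to remap")
    free = np.array(sorted(set(range(n)) - used), dtype=np.int64)
    new_nodes = rng.choice(free, size=n_inputs + n_outputs, replace=False)
    in_ch = rng.choice(len(coupling.input_nodes), size=n_inputs, replace=False)
    out_ch = rng.choice(len(coupling.output_nodes), size=n_outputs, replace=False)
    inputs = list(coupling.input_nodes)
    outputs = list(coupling.output_nodes)
    for ch, node in zip(in_ch, new_nodes[:n_inputs]):
        inputs[ch] = int(node)
    for ch, node in zip(out_ch, new_nodes[n_inputs:]):
        outputs[ch] = int(node)
    return Coupling(tuple(inputs), tuple(outputs))
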