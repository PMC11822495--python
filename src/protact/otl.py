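"""Oscillatory Threshold Logic (OTL).

Analog voltage oscillations are converted to binary logic by amplitude
thresholding with a minimum-duration constraint: a sample is HIGH only when
the voltage exceeds the discrimination threshold theta continuously for at
least tau_min, which filters out transient fluctuations.  Thresholded bit
streams then compose through ordinary Boolean gates; the half adder uses an
OR-gate sum and an AND-gate carry (the OR-sum convention is kept as printed
in the source truth table, with a conventional XOR variant behind a flag).

The full pipeline takes two input channels and two output channels,
thresholds each, and forms the overall OTL stream as the OR of the two
output gate streams, so a sustained suprathreshold event in either output
channel registers a positive OTL result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import VoltageTrace

__all__ = [
    "ThresholdSpec", "BitStream", "GateStateMatrix",
    "threshold", "gate_or", "gate_and", "gate_not", "half_adder",
    "otl_pipeline", "truth_table_report",
    "write_gate_matrix", "read_gate_matrix", "plot_gate_heatmap",
    "THETA_DEFAULT", "THETA_REST_DERIVED",
]

#: discrimination threshold stated for the recordings, volts
THETA_DEFAULT = 0.5
#: alternative preset: resting potential (~0.0212 V) + 2 sd (2 x 0.0176 V)
THETA_REST_DERIVED = 0.0212 + 2 * 0.0176

GATE_LABELS = ("V1_in", "W1_in", "V1_out", "W1_out", "OTL")


@dataclass(frozen=True)
class ThresholdSpec:
    """Thresholding parameters: level theta (V) and minimum duration (s)."""
    theta: float = THETA_DEFAULT
    tau_min: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_min < 0:
            raise ValueError("tau_min must be nonnegative")


@dataclass(frozen=True)
class BitStream:
    """Binary sequence sampled at interval dt."""
    bits: np.ndarray
    dt: float
    origin: str = ""

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        object.__setattr__(self, "bits", bits.astype(np.uint8))

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class GateStateMatrix:
    """Time x gate binary matrix over {V1_in, W1_in, V1_out, W1_out, OTL}."""
    states: np.ndarray          # shape (n_time, 5), uint8
    dt: float
    gates: tuple = GATE_LABELS

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.uint8)
        if states.ndim != 2 or states.shape[1] != len(self.gates):
            raise ValueError(
                f"states must be (time, {len(self.gates)}), got {states.shape}")
        object.__setattr__(self, "states", states)

    def column(self, gate: str) -> np.ndarray:
        return self.states[:, self.gates.index(gate)]


def _sustained_mask(above: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only runs of True at least ``min_run`` samples long."""
    if min_run <= 1:
        return above.copy()
    padded = np.concatenate(([False], above, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    out = np.zeros_like(above)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            out[s:e] = True
    return out


def threshold(trace: VoltageTrace, spec: ThresholdSpec) -> BitStream:
    """Duration-constrained thresholding of a voltage trace.

    A sample maps to 1 iff ``v > theta`` (strictly; a value exactly at the
    threshold does not surpass it) holds continuously for at least
    ``tau_min`` seconds around it.  With ``tau_min = 0`` this reduces to a
    plain comparison.
    """
    above = trace.v > spec.theta
    min_run = int(np.ceil(spec.tau_min / trace.dt)) if spec.tau_min > 0 else 1
    bits = _sustained_mask(above, min_run)
    return BitStream(bits=bits.astype(np.uint8), dt=trace.dt,
                     origin=trace.label)


def _check_aligned(a: BitStream, b: BitStream) -> None:
    if len(a) != len(b):
        raise ValueError(f"bit streams differ in length: {len(a)} vs {len(b)}")
    if abs(a.dt - b.dt) > 1e-12 * max(a.dt, b.dt):
        raise ValueError(f"bit streams differ in dt: {a.dt} vs {b.dt}")


def gate_or(a: BitStream, b: BitStream) -> BitStream:
    """Elementwise OR — the half-adder sum output convention."""
    _check_aligned(a, b)
    return BitStream(bits=a.bits | b.bits, dt=a.dt,
                     origin=f"OR({a.origin},{b.origin})")


def gate_and(a: BitStream, b: BitStream) -> BitStream:
    """Elementwise AND — the half-adder carry output."""
    _check_aligned(a, b)
    return BitStream(bits=a.bits & b.bits, dt=a.dt,
                     origin=f"AND({a.origin},{b.origin})")


def gate_not(a: BitStream) -> BitStream:
    """Elementwise bit flip."""
    return BitStream(bits=1 - a.bits, dt=a.dt, origin=f"NOT({a.origin})")


def half_adder(a: BitStream, b: BitStream,
               sum_mode: str = "or") -> tuple[BitStream, BitStream]:
    """Half adder on two bit streams.

    The printed truth table defines the sum through an OR gate, which is
    nonstandard; ``sum_mode="xor"`` selects the conventional exclusive-or
    sum instead.  The carry is always the AND.
    """
    _check_aligned(a, b)
    if sum_mode == "or":
        s = gate_or(a, b)
    elif sum_mode == "xor":
        s = BitStream(bits=a.bits ^ b.bits, dt=a.dt,
                      origin=f"XOR({a.origin},{b.origin})")
    else:
        raise ValueError(f"sum_mode must be 'or' or 'xor', got {sum_mode!r}")
    return s, gate_and(a, b)


def otl_pipeline(v1_in: VoltageTrace, w1_in: VoltageTrace,
                 v1_out: VoltageTrace, w1_out: VoltageTrace,
                 spec: ThresholdSpec) -> GateStateMatrix:
    """Threshold four channels and compose the overall OTL gate.

    Each channel's gate stream is the duration-constrained threshold bits
    AND the plain-comparison bits of the same channel (the duration rule
    already implies the comparison, so the conjunction is recorded for
    fidelity to the gating equations rather than for effect).  The OTL
    column is the OR of the two output gate streams.
    """
    traces = (v1_in, w1_in, v1_out, w1_out)
    n = len(v1_in)
    for tr in traces[1:]:
        if len(tr) != n or abs(tr.dt - v1_in.dt) > 1e-12 * v1_in.dt:
            raise ValueError("all four traces must share length and dt")
    cols = []
    for tr in traces:
        sustained = threshold(tr, spec).bits
        plain = (tr.v > spec.theta).astype(np.uint8)
        cols.append(sustained & plain)
    otl = cols[2] | cols[3]
    states = np.column_stack(cols + [otl])
    return GateStateMatrix(states=states, dt=v1_in.dt)


def truth_table_report(matrix: GateStateMatrix,
                       sample_steps) -> pd.DataFrame:
    """Tabulate gate states at the requested time steps (0-based indices)."""
    steps = list(sample_steps)
    n = matrix.states.shape[0]
    for s in steps:
        if not (0 <= s < n):
            raise IndexError(f"time step {s} out of range [0, {n})")
    data = {"time_step": steps}
    for j, g in enumerate(matrix.gates):
        data[g] = [int(matrix.states[s, j]) for s in steps]
    return pd.DataFrame(data)


def write_gate_matrix(matrix: GateStateMatrix, path: str | Path) -> None:
    """Export as CSV: one time_s column plus one column per gate."""
    df = pd.DataFrame(matrix.states, columns=list(matrix.gates))
    df.insert(0, "time_s", matrix.dt * np.arange(len(df)))
    df.to_csv(path, index=False)


def read_gate_matrix(path: str | Path) -> GateStateMatrix:
    df = pd.read_csv(path)
    gates = tuple(c for c in df.columns if c != "time_s")
    dt = float(np.median(np.diff(df["time_s"]))) if len(df) > 1 else 1.0
    return GateStateMatrix(states=df[list(gates)].to_numpy(dtype=np.uint8),
                           dt=dt, gates=gates)


def plot_gate_heatmap(matrix: GateStateMatrix, path: str | Path) -> None:
    """Render the gate-state matrix as a red(HIGH)/black(LOW) heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.imshow(matrix.states.T, aspect="auto", interpolation="nearest",
              cmap=ListedColormap(["black", "red"]), vmin=0, vmax=1)
    ax.set_yticks(range(len(matrix.gates)), matrix.gates)
    ax.set_xlabel("time step")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
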