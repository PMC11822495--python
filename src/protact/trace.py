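"""Uniformly sampled voltage time series and its CSV dialect.

A :class:`VoltageTrace` is the currency every stage of the pipeline trades
in: chaotic drives, surrogate responses and deposited recordings are all
two-column (time in seconds, voltage in volts) series on a uniform grid.

The on-disk dialect is a plain ``time_s,voltage_V`` CSV, optionally preceded
by a single ``#``-prefixed line carrying a JSON metadata header (the drive
specification, seeds, provenance).  Headerless two-column TSV exports from
ADC loggers are auto-detected on read.  Unicode minus and en-dash signs, as
they appear in published tables, are normalized to ASCII.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["VoltageTrace", "TraceValidationError", "TraceParseError",
           "read_trace", "write_trace"]

#: relative tolerance on time-grid uniformity
_DT_RTOL = 1e-9


class TraceValidationError(ValueError):
    """Raised when a time series violates the VoltageTrace invariants."""


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled voltage time series.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing with uniform step ``dt``.
    v : ndarray
        Voltages in volts, same length as ``t``.
    dt : float
        Sampling interval in seconds.
    label : str
        Free-text description (e.g. ``"logistic mu=3.8"``).
    meta : dict
        Arbitrary JSON-serializable provenance (drive parameters, seed, ...).
    """

    t: np.ndarray
    v: np.ndarray
    dt: float
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise TraceValidationError(
                f"t and v must be 1-D of equal length, got {t.shape} / {v.shape}")
        if len(t) < 2:
            raise TraceValidationError("a trace needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            bad = int(np.flatnonzero(~np.isfinite(v))[0]) if not np.all(
                np.isfinite(v)) else int(np.flatnonzero(~np.isfinite(t))[0])
            raise TraceValidationError(f"non-finite value at row {bad}")
        if not (self.dt > 0) or not math.isfinite(self.dt):
            raise TraceValidationError(f"dt must be positive, got {self.dt}")
        steps = np.diff(t)
        if np.any(steps <= 0):
            bad = int(np.flatnonzero(steps <= 0)[0])
            raise TraceValidationError(
                f"time must be strictly increasing (violated at row {bad + 1})")
        if np.max(np.abs(steps - self.dt)) >= _DT_RTOL * max(self.dt, 1.0):
            raise TraceValidationError(
                "non-uniform sampling grid; resample to a fixed dt before "
                "constructing a VoltageTrace")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Total span ``t[-1] - t[0]`` in seconds."""
        return float(self.t[-1] - self.t[0])

    @classmethod
    def from_samples(cls, v: np.ndarray, dt: float, t0: float = 0.0,
                     label: str = "", meta: dict | None = None) -> "VoltageTrace":
        """Build a trace from voltages on an implicit uniform grid."""
        v = np.asarray(v, dtype=float)
        t = t0 + dt * np.arange(len(v))
        return cls(t=t, v=v, dt=float(dt), label=label, meta=meta or {})

    def with_values(self, v: np.ndarray, label: str | None = None,
                    meta: dict | None = None) -> "VoltageTrace":
        """Return a copy sharing this trace's time grid with new voltages."""
        return VoltageTrace(t=self.t.copy(), v=np.asarray(v, dtype=float),
                            dt=self.dt,
                            label=self.label if label is None else label,
                            meta=dict(self.meta) if meta is None else meta)


_UNICODE_MINUS = {"−": "-", "–": "-", "—": "-"}


def _normalize_signs(text: str) -> str:
    for k, a in _UNICODE_MINUS.items():
        text = text.replace(k, a)
    return text


def write_trace(trace: VoltageTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,voltage_V`` CSV with a JSON header line."""
    path = Path(path)
    header = {"label": trace.label, "dt": trace.dt, **trace.meta}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("time_s,voltage_V\n")
        df = pd.DataFrame({"time_s": trace.t, "voltage_V": trace.v})
        df.to_csv(fh, index=False, header=False, float_format="%.12g",
                  lineterminator="\n")


def read_trace(path: str | Path, dialect: str = "auto") -> VoltageTrace:
    """Read a two-column voltage trace.

    Parameters
    ----------
    dialect : {"auto", "csv", "tsv"}
        ``auto`` sniffs the delimiter from the first data line; the explicit
        dialects force comma or tab separation.

    Raises
    ------
    TraceParseError
        Malformed rows (with line number), NaNs, or non-monotone time.
    """
    path = Path(path)
    raw = _normalize_signs(path.read_text(encoding="utf-8"))
    lines = raw.splitlines()
    meta: dict = {}
    start = 0
    if lines and lines[0].lstrip().startswith("#"):
        try:
            meta = json.loads(lines[0].lstrip()[1:])
        except json.JSONDecodeError:
            meta = {"header": lines[0].lstrip("# ").strip()}
        start = 1
    # drop a textual column-header line if present
    if start < len(lines):
        first = lines[start].strip()
        if first and not _looks_numeric_row(first):
            start += 1

    if dialect == "csv":
        sep = ","
    elif dialect == "tsv":
        sep = "\t"
    elif dialect == "auto":
        probe = lines[start] if start < len(lines) else ""
        sep = "\t" if "\t" in probe else ("," if "," in probe else r"\s+")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    body = "\n".join(lines[start:])
    try:
        df = pd.read_csv(io.StringIO(body), sep=sep, header=None,
                         engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TraceParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    for name, col in (("time", t), ("voltage", v)):
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            row = int(bad[0]) + start + 1  # 1-based file line
            raise TraceParseError(
                f"{path}: non-numeric or missing {name} at line {row}")

    steps = np.diff(t)
    if np.any(steps <= 0):
        row = int(np.flatnonzero(steps <= 0)[0]) + start + 2
        raise TraceParseError(f"{path}: time not strictly increasing at line {row}")
    dt = float(meta.get("dt", np.median(steps)))
    if np.max(np.abs(steps - dt)) >= _DT_RTOL * max(dt, 1.0):
        raise TraceParseError(
            f"{path}: non-uniform timestamps (median step {np.median(steps):g}); "
            "resample to a fixed interval before analysis")
    label = str(meta.pop("label", path.stem))
    meta.pop("dt", None)
    return VoltageTrace(t=t, v=v, dt=dt, label=label, meta=meta)


def _looks_numeric_row(line: str) -> bool:
    head = line.replace(",", " ").replace("\t", " ").split()
    if not head:
        return False
    try:
        float(head[0])
        return True
    except ValueError:
        return False
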