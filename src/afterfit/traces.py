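"""Sampled haemodynamic time series and their CSV representation.

The internal unit system is fixed: time in ms, pressure in kPa, flow in
ml/ms, volume in ml.  Other clinical units (mmHg, s) are converted at the
I/O boundary only, with explicit factors.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Conversion factor from mmHg to kPa (exact to the definition 1 mmHg = 133.322 Pa).
KPA_PER_MMHG = 0.133322

VALID_UNITS = ("kPa", "ml/ms", "ml")


@dataclass(frozen=True)
class HaemoTrace:
    """A sampled time series over (typically) one cardiac cycle.

    Parameters
    ----------
    t : array of sample times in ms, strictly increasing.
    v : array of sample values (unit given by ``unit``).
    unit : one of ``"kPa"`` (pressure), ``"ml/ms"`` (flow), ``"ml"`` (volume).
    cycle : whether the trace spans exactly one cardiac cycle starting at 0.
    """

    t: np.ndarray
    v: np.ndarray
    unit: str
    cycle: bool = field(default=True)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("t and v must be 1-d arrays of equal length")
        if t.size < 4:
            raise ValueError("a trace needs at least 4 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(f"time vector not strictly increasing at row {i + 1}")

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Span of the trace in ms."""
        return float(self.t[-1] - self.t[0])

    def value_at(self, time: float) -> float:
        """Linearly interpolated value at ``time`` (ms)."""
        return float(np.interp(time, self.t, self.v))

    def resample(self, t_new: np.ndarray) -> "HaemoTrace":
        t_new = np.asarray(t_new, dtype=float)
        return HaemoTrace(t_new, np.interp(t_new, self.t, self.v), self.unit, self.cycle)

    def integral(self) -> float:
        """Trapezoid integral of v over t (e.g. stroke volume for a flow trace)."""
        return float(np.trapezoid(self.v, self.t))


def read_trace(path: str | Path, expected_unit: str, *, declared_unit: str | None = None,
               time_unit: str = "ms") -> HaemoTrace:
    """Read a trace CSV with header ``t_ms,value``.

    ``declared_unit`` may be ``"mmHg"`` (converted to kPa) or one of the
    internal units; ``time_unit`` may be ``"s"`` (converted to ms).  A unit
    mismatch without a declared conversion raises ``ValueError``.
    """
    path = Path(path)
    raw = path.read_text()
    if not raw.strip():
        raise ValueError(f"{path}: empty file")
    t, v = _parse_csv(raw, path)
    if time_unit == "s":
        t = t * 1000.0
    elif time_unit != "ms":
        raise ValueError(f"unsupported time unit {time_unit!r}")
    unit = declared_unit or expected_unit
    if unit == "mmHg":
        if expected_unit != "kPa":
            raise ValueError("mmHg input only converts to kPa traces")
        v = v * KPA_PER_MMHG
        unit = "kPa"
    if unit != expected_unit:
        raise ValueError(f"{path}: declared unit {unit!r} does not match expected "
                         f"{expected_unit!r} and no conversion is defined")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        # i indexes the step; the offending sample is i+1, at file line i+3
        raise ValueError(f"{path}: non-monotone time at data row {i + 3}")
    return HaemoTrace(t, v, expected_unit)


def write_trace(trace: HaemoTrace, path: str | Path) -> None:
    """Write a trace as a two-column CSV with header ``t_ms,value``."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("t_ms,value\n")
    for ti, vi in zip(trace.t, trace.v):
        buf.write(f"{float(ti)!r},{float(vi)!r}\n")
    path.write_text(buf.getvalue())


def _parse_csv(raw: str, path: Path) -> tuple[np.ndarray, np.ndarray]:
    lines = [ln for ln in raw.splitlines() if ln.strip() and not ln.startswith("#")]
    header = [h.strip() for h in lines[0].split(",")]
    if header[:2] != ["t_ms", "value"]:
        raise ValueError(f"{path}: expected header 't_ms,value', got {lines[0]!r}")
    t, v = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed row {i}: {ln!r}")
        t.append(float(parts[0]))
        v.append(float(parts[1]))
    return np.asarray(t), np.asarray(v)
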