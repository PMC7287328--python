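"""Trace pre-processing and extraction of the point measurements driving fitting.

The fitting procedure deliberately uses only three characteristic pressures —
valve-opening pressure p_op, peak pressure p_peak, and valve-closing pressure
p_cl — rather than the full pressure trace, so that it applies equally to
patients without invasive catheter recordings.  This module turns traces (or
cuff measurements) into those features plus per-cycle summary metrics.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .traces import HaemoTrace

#: Fraction of peak flow used to detect ejection onset/offset.
EJECTION_THRESHOLD_FRAC = 0.02


@dataclass(frozen=True)
class PressureFeatures:
    """Characteristic pressure triple (kPa), plus simulated end-of-cycle pressure.

    p_ed is the pressure at the end of the cycle; for measured features it is
    usually unknown (None), for simulated ones it closes the periodicity
    residual against the measured p_op.
    """

    p_op: float
    p_peak: float
    p_cl: float
    p_ed: float | None = None

    def __post_init__(self) -> None:
        for name in ("p_op", "p_peak", "p_cl"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {val}")
        if self.p_ed is not None and (not np.isfinite(self.p_ed) or self.p_ed <= 0):
            raise ValueError(f"p_ed must be finite and > 0, got {self.p_ed}")

    def with_noise(self, rng: np.random.Generator, sd: float = 0.0,
                   rel: float = 0.0) -> "PressureFeatures":
        """Gaussian perturbation of the measured triple.

        ``sd`` is an absolute standard deviation in kPa, ``rel`` a relative
        one; the two add in quadrature per component.
        """
        def perturb(x: float) -> float:
            sigma = float(np.hypot(sd, rel * x))
            return x + sigma * rng.standard_normal()

        return replace(self, p_op=perturb(self.p_op), p_peak=perturb(self.p_peak),
                       p_cl=perturb(self.p_cl))


@dataclass(frozen=True)
class CycleMetrics:
    """Per-cycle summary quantities."""

    T_cycle: float      # ms
    T_dias: float       # diastolic duration, ms
    MAP: float          # mean arterial pressure, kPa
    SV: float           # stroke volume, ml
    q_peak: float       # ml/ms
    t_cl: float         # valve-closure time from cycle start, ms
    t_onset: float = 0.0  # ejection onset, ms

    def __post_init__(self) -> None:
        if not (0 < self.T_dias < self.T_cycle):
            raise ValueError(f"need 0 < T_dias < T_cycle, got {self.T_dias}, {self.T_cycle}")
        if self.SV <= 0 or self.MAP <= 0:
            raise ValueError("SV and MAP must be positive")

    @property
    def cardiac_output(self) -> float:
        """Mean flow SV/T_cycle in ml/ms."""
        return self.SV / self.T_cycle


@dataclass(frozen=True)
class CuffRecord:
    """Brachial cuff pressures plus echo-estimated trans-valvular drop (kPa)."""

    p_dia_cuff: float
    p_sys_cuff: float
    dp_av_m: float = 0.0

    def __post_init__(self) -> None:
        if not (self.p_sys_cuff > self.p_dia_cuff > 0):
            raise ValueError("need p_sys_cuff > p_dia_cuff > 0")
        if self.dp_av_m < 0:
            raise ValueError("dp_av_m must be non-negative")


@dataclass(frozen=True)
class CuffEstimate:
    """Pressure features estimated non-invasively, with the LV peak estimate."""

    features: PressureFeatures
    p_lv_est: float  # estimated LV peak systolic pressure, kPa


def ejection_window(q: HaemoTrace, threshold_frac: float = EJECTION_THRESHOLD_FRAC
                    ) -> tuple[int, int, int]:
    """Indices (onset, peak, closure) of the ejection window of a flow trace.

    Onset is the first sample at or above ``threshold_frac * q_peak``; closure
    is the first sample after the peak back at or below the threshold.
    """
    v = q.v
    q_peak = float(np.max(v))
    if q_peak <= 0:
        raise ValueError("flat or non-positive flow: no detectable ejection")
    thr = threshold_frac * q_peak
    i_peak = int(np.argmax(v))
    above = np.nonzero(v[: i_peak + 1] >= thr)[0]
    i_on = int(above[0]) if above.size else i_peak
    after = np.nonzero(v[i_peak:] <= thr)[0]
    i_cl = int(i_peak + after[0]) if after.size else q.n - 1
    return i_on, i_peak, i_cl


def ejection_times(q: HaemoTrace, threshold_frac: float = EJECTION_THRESHOLD_FRAC
                   ) -> tuple[float, float, float]:
    """Times (onset, peak, closure) of the ejection window, in ms.

    The threshold of :func:`ejection_window` only locates the crossing
    segments robustly; the reported times are the linear extrapolations of
    those segments to the zero-flow baseline.  This makes the event times
    independent of the sampling grid and removes the threshold-induced lag
    between "flow exceeds 2% of peak" and the actual opening/closure of the
    valve, so the onset pressure is the pressure where ejection truly starts.
    """
    i_on, i_peak, i_cl = ejection_window(q, threshold_frac)
    t, v = q.t, q.v

    def zero_cross(i: int, j: int, lo: float, hi: float) -> float:
        # extrapolate the segment (i, j) to v = 0, clamped to [lo, hi]
        if v[j] == v[i]:
            return float(np.clip(t[j], lo, hi))
        tz = t[i] + (0.0 - v[i]) / (v[j] - v[i]) * (t[j] - t[i])
        return float(np.clip(tz, lo, hi))

    if i_on > 0:
        t_on = zero_cross(i_on - 1, i_on, float(t[0]), float(t[i_on]))
    else:
        t_on = float(t[0])
    if i_cl > i_peak:
        t_cl = zero_cross(i_cl - 1, i_cl, float(t[i_cl - 1]), float(t[-1]))
    else:
        t_cl = float(t[i_cl])
    return t_on, float(t[i_peak]), t_cl


def volume_to_flow(V: HaemoTrace, threshold_frac: float = EJECTION_THRESHOLD_FRAC
                   ) -> HaemoTrace:
    """Aortic flow q = -dV/dt from an LV volume trace.

    The derivative (central differences, one-sided at the endpoints) is
    clamped to zero outside the detected ejection window: the valve is a
    diode, and diastolic filling does not cross it.
    """
    if V.unit != "ml":
        raise ValueError(f"volume trace must be in ml, got {V.unit}")
    qv = -np.gradient(V.v, V.t)
    if np.max(qv) <= 0:
        return HaemoTrace(V.t, np.zeros_like(qv), "ml/ms", V.cycle)
    q = HaemoTrace(V.t, np.clip(qv, 0.0, None), "ml/ms", V.cycle)
    i_on, _, i_cl = ejection_window(q, threshold_frac)
    v = q.v.copy()
    v[:i_on] = 0.0
    v[i_cl + 1:] = 0.0
    return HaemoTrace(V.t, v, "ml/ms", V.cycle)


def _circular_shift(t: np.ndarray, v: np.ndarray, t0: float) -> np.ndarray:
    """Values of the periodic extension at t + t0 (shift left by t0)."""
    T = t[-1] - t[0]
    t0 = float(np.mod(t0, T))
    if t0 == 0.0:
        return v.copy()
    # periodic continuation over a second cycle avoids a wrap discontinuity
    t_ext = np.concatenate([t, t[1:] + T])
    v_ext = np.concatenate([v, v[1:]])
    return np.interp(t + t0, t_ext, v_ext)


def preprocess_traces(p: HaemoTrace, q: HaemoTrace, target_T_cycle: float,
                      threshold_frac: float = EJECTION_THRESHOLD_FRAC
                      ) -> tuple[HaemoTrace, HaemoTrace]:
    """Synchronize and rescale a pressure/flow pair onto one common cycle.

    Each trace is treated as one (possibly misaligned) cardiac cycle.  Both
    are circularly shifted so that ejection onset — the threshold upcross of
    q, and the pressure minimum marking the foot of the upstroke — sits at
    t = 0, resampled to a common uniform grid, and uniformly time-scaled to
    ``target_T_cycle``.  Flow amplitude is divided by the time-scale factor so
    the stroke volume is preserved.
    """
    T_p, T_q = p.duration, q.duration
    if abs(T_p - T_q) / max(T_p, T_q) > 0.5:
        raise ValueError(f"cycle lengths differ by more than 50%: {T_p} vs {T_q} ms")
    if target_T_cycle <= 0:
        raise ValueError("target_T_cycle must be positive")

    def snap(t0: float, trace: HaemoTrace) -> float:
        # shifts below half a sample step are indistinguishable from alignment
        T = trace.duration
        t0 = float(np.mod(t0, T))
        h = T / (trace.n - 1)
        return 0.0 if min(t0, T - t0) < h / 2 else t0

    t_q0 = snap(ejection_times(q, threshold_frac)[0] - float(q.t[0]), q)
    q_shift = _circular_shift(q.t, q.v, t_q0)
    t_p0 = snap(float(p.t[int(np.argmin(p.v))] - p.t[0]), p)
    p_shift = _circular_shift(p.t, p.v, t_p0)

    n = max(p.n, q.n)
    grid = np.linspace(0.0, target_T_cycle, n)
    sp = target_T_cycle / T_p
    sq = target_T_cycle / T_q
    p_out = np.interp(grid / sp, p.t - p.t[0], p_shift)
    q_out = np.interp(grid / sq, q.t - q.t[0], q_shift) / sq
    return (HaemoTrace(grid, p_out, "kPa"), HaemoTrace(grid, q_out, "ml/ms"))


def extract_features(p: HaemoTrace, q: HaemoTrace,
                     threshold_frac: float = EJECTION_THRESHOLD_FRAC
                     ) -> tuple[PressureFeatures, CycleMetrics]:
    """Point pressures and cycle metrics from aligned cycle traces.

    p_op is the pressure at ejection onset, p_peak the grid maximum, p_cl the
    pressure at valve closure (flow back at the threshold after its peak),
    and p_ed the pressure at the end of the cycle.
    """
    if p.unit != "kPa" or q.unit != "ml/ms":
        raise ValueError("expected a kPa pressure trace and an ml/ms flow trace")
    if np.any(p.v <= 0):
        raise ValueError("pressure trace must be strictly positive")
    t_on_abs, _, t_cl_abs = ejection_times(q, threshold_frac)
    t_onset = t_on_abs - float(q.t[0])
    t_cl = t_cl_abs - float(q.t[0])
    T_cycle = p.duration

    feats = PressureFeatures(
        p_op=p.value_at(p.t[0] + t_onset),
        p_peak=float(np.max(p.v)),
        p_cl=p.value_at(p.t[0] + t_cl),
        p_ed=float(p.v[-1]),
    )
    metrics = CycleMetrics(
        T_cycle=T_cycle,
        T_dias=T_cycle - (t_cl - t_onset),
        MAP=p.integral() / T_cycle,
        SV=q.integral(),
        q_peak=float(np.max(q.v)),
        t_cl=t_cl,
        t_onset=t_onset,
    )
    return feats, metrics


def estimate_from_cuff(cuff: CuffRecord, fraction_cl: float = 0.7) -> CuffEstimate:
    """Pressure features from cuff measurements when no catheter trace exists.

    p_op is taken as the diastolic cuff pressure and the aortic p_peak as the
    systolic cuff pressure; the LV peak estimate adds the echo trans-valvular
    drop on top.  p_cl is placed a fixed fraction of the pulse pressure above
    diastolic (a dicrotic-notch heuristic standing in for empirical reference
    data).
    """
    if not 0 < fraction_cl < 1:
        raise ValueError("fraction_cl must lie in (0, 1)")
    pulse = cuff.p_sys_cuff - cuff.p_dia_cuff
    feats = PressureFeatures(
        p_op=cuff.p_dia_cuff,
        p_peak=cuff.p_sys_cuff,
        p_cl=cuff.p_dia_cuff + fraction_cl * pulse,
    )
    return CuffEstimate(features=feats, p_lv_est=cuff.p_sys_cuff + cuff.dp_av_m)
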