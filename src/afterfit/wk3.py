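"""Three-element Windkessel (Wk3) afterload model: parameters and forward solver.

The model lumps the arterial tree into a characteristic aortic impedance Z in
series with a parallel resistance R / compliance C pair.  Given the flow q(t)
across the aortic valve, the aortic pressure p(t) obeys

    dp/dt = (1/C + Z/(R C)) q + Z dq/dt - p/(R C),

with all quantities in the kPa / ms / ml unit system.  The single time
constant tau = R*C (hundreds of ms) makes the equation non-stiff, so a
fixed-step classical 4th-order Runge-Kutta scheme with a 1 ms default step is
used.  Because the right-hand side is linear in p, each RK4 step reduces to a
scalar linear recurrence p[n+1] = A*p[n] + B[n]; the recurrence is evaluated
with a first-order IIR filter, which is exactly the RK4 iteration evaluated
in C speed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .traces import HaemoTrace

DEFAULT_STEP_MS = 1.0


@dataclass(frozen=True)
class Wk3Params:
    """Windkessel parameter triple.

    Z : characteristic aortic impedance, kPa ms/ml
    R : total arterial resistance, kPa ms/ml
    C : total arterial compliance, ml/kPa
    """

    Z: float
    R: float
    C: float

    def __post_init__(self) -> None:
        for name in ("Z", "R", "C"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {val}")

    @property
    def tau(self) -> float:
        """Diastolic decay time constant R*C in ms."""
        return self.R * self.C

    def as_array(self) -> np.ndarray:
        return np.array([self.Z, self.R, self.C])


@dataclass(frozen=True)
class ValveParams:
    """Aortic valve as a resistive diode.

    Zv : additional valve impedance, kPa ms/ml
    dp_av : peak trans-valvular pressure drop, kPa
    q_peak : peak aortic flow, ml/ms
    """

    Zv: float
    dp_av: float
    q_peak: float

    def __post_init__(self) -> None:
        if self.Zv < 0 or self.dp_av < 0:
            raise ValueError("Zv and dp_av must be non-negative")
        if self.q_peak <= 0:
            raise ValueError("q_peak must be positive")


def diastolic_decay(p0: float, params: Wk3Params, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form zero-flow pressure decay p0*exp(-t/(R*C))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if p0 <= 0:
        raise ValueError("p0 must be positive")
    out = p0 * np.exp(-t / params.tau)
    return float(out) if out.ndim == 0 else out


class FlowGrid:
    """Flow trace prepared on the uniform solver grid.

    Precomputes q and dq/dt on solver nodes and RK4 midpoints so that
    repeated solves with different parameters (the inner loop of fitting)
    reuse the interpolation work.  dq/dt is formed by central finite
    differences on the *sample* grid (one-sided at the endpoints), optionally
    moving-average smoothed, then linearly interpolated.
    """

    def __init__(self, q: HaemoTrace, step: float = DEFAULT_STEP_MS,
                 smooth_window: int = 0) -> None:
        if q.unit != "ml/ms":
            raise ValueError(f"flow trace must be in ml/ms, got {q.unit}")
        T = q.t[-1] - q.t[0]
        if T <= 0:
            raise ValueError("cycle duration must be positive")
        n_steps = max(int(round(T / step)), 4)
        self.h = T / n_steps
        self.t = q.t[0] + self.h * np.arange(n_steps + 1)
        ts, qs = q.t, q.v
        dqdt = np.gradient(qs, ts)
        if smooth_window > 1:
            kernel = np.ones(smooth_window) / smooth_window
            dqdt = np.convolve(dqdt, kernel, mode="same")
        t_half = self.t[:-1] + self.h / 2
        self.q_node = np.interp(self.t, ts, qs)
        self.q_half = np.interp(t_half, ts, qs)
        self.dq_node = np.interp(self.t, ts, dqdt)
        self.dq_half = np.interp(t_half, ts, dqdt)

    def step_coeffs(self, params: Wk3Params | tuple[float, float, float]
                    ) -> tuple[float, np.ndarray]:
        """Per-step RK4 recurrence coefficients: p[n+1] = A*p[n] + B[n]."""
        if isinstance(params, Wk3Params):
            Z, R, C = params.Z, params.R, params.C
        else:
            Z, R, C = params
        tau = R * C
        h = self.h
        a = h / tau
        A = 1.0 - a + a * a / 2 - a**3 / 6 + a**4 / 24
        coef = 1.0 / C + Z / tau
        f_node = coef * self.q_node + Z * self.dq_node
        f_half = coef * self.q_half + Z * self.dq_half
        B = (h / 6.0) * ((1.0 - a + a * a / 2 - a**3 / 4) * f_node[:-1]
                         + (4.0 - 2.0 * a + a * a / 2) * f_half
                         + f_node[1:])
        return A, B

    def propagate(self, A: float, B: np.ndarray, p0: float) -> np.ndarray:
        """Apply the linear recurrence from p(0) = p0 over the whole grid."""
        x = np.empty(self.t.size)
        x[0] = p0
        x[1:] = B
        return lfilter([1.0], [1.0, -A], x)

    def solve(self, params: Wk3Params | tuple[float, float, float], p0: float) -> np.ndarray:
        """Pressure on the solver grid for the given parameters, p(0)=p0."""
        A, B = self.step_coeffs(params)
        return self.propagate(A, B, p0)


def solve_wk3(q: HaemoTrace, params: Wk3Params, p0: float,
              step: float = DEFAULT_STEP_MS, smooth_window: int = 0) -> HaemoTrace:
    """Solve the Wk3 equation for aortic pressure over one cycle.

    Parameters
    ----------
    q : flow trace in ml/ms spanning one cycle.
    params : Wk3 parameter triple.
    p0 : initial pressure in kPa (clinically, the valve-opening pressure).
    step : solver step in ms; the output grid is uniform with this nominal step.

    Returns
    -------
    HaemoTrace of pressure in kPa on a uniform grid over [0, T_cycle].
    """
    if not np.isfinite(p0) or p0 <= 0:
        raise ValueError(f"p0 must be finite and positive, got {p0}")
    grid = FlowGrid(q, step=step, smooth_window=smooth_window)
    return HaemoTrace(grid.t, grid.solve(params, p0), "kPa")


def periodic_initial_pressure(q: HaemoTrace, params: Wk3Params,
                              step: float = DEFAULT_STEP_MS) -> float:
    """Initial pressure for which the cycle solution is periodic, p(T) = p(0).

    Uses linearity: p(T) = A_tot*p(0) + B_tot, so p(0) = B_tot/(1 - A_tot).
    """
    grid = FlowGrid(q, step=step)
    b_tot = grid.solve(params, 0.0)[-1]
    a_tot = grid.solve(params, 1.0)[-1] - b_tot
    if not 0 < a_tot < 1:
        raise ValueError("no stable periodic solution (check cycle length and tau)")
    return float(b_tot / (1.0 - a_tot))
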