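"""Fitting objective: weighted pressure-feature misfit plus physiological penalty.

The misfit compares three simulated quantities against the measured triple:
peak pressure against measured peak, end-of-cycle pressure against measured
valve-opening pressure (a periodicity residual), and valve-closing pressure
against its measurement.  Physiological plausibility is enforced through five
inequality groups (on Z, C<=R, the decay constant relative to diastole, and
the closing pressure) folded in as quadratic max-penalties.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import CycleMetrics, PressureFeatures, ejection_times
from .traces import HaemoTrace
from .wk3 import DEFAULT_STEP_MS, FlowGrid, Wk3Params


@dataclass(frozen=True)
class CostWeights:
    """Weights omega_i = gamma_i / m_i^2 of the three cost terms.

    With the default gamma_i = 1 and m_i set to the measured pressures, each
    term behaves like a squared relative error, so all three contribute on
    the same scale.
    """

    gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ref_means: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gamma) or any(m <= 0 for m in self.ref_means):
            raise ValueError("gamma and ref_means must be positive")

    @property
    def omega(self) -> tuple[float, float, float]:
        return tuple(g / m**2 for g, m in zip(self.gamma, self.ref_means))

    @classmethod
    def from_measured(cls, measured: PressureFeatures,
                      gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> "CostWeights":
        """Reference means taken from the measured triple (peak, opening, closing)."""
        return cls(gamma=gamma, ref_means=(measured.p_peak, measured.p_op, measured.p_cl))


@dataclass(frozen=True)
class ConstraintBounds:
    """Bounds b_i of the physiological inequality groups and penalty scale kappa.

    The defaults are configurable stand-ins spanning generous physiological
    ranges: RC/T_dias within [b0, b1], p_cl at least b2*MAP and at least b3.
    """

    b0: float = 0.5
    b1: float = 6.0
    b2: float = 0.7
    b3: float = 4.0     # kPa
    kappa: float = 1e4

    def __post_init__(self) -> None:
        if not self.b0 < self.b1:
            raise ValueError("need b0 < b1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def cost(measured: PressureFeatures, simulated: PressureFeatures, w: CostWeights) -> float:
    """Three-term weighted squared-residual misfit.

    J = w0/2 (p_peak_m - p_peak)^2 + w1/2 (p_op_m - p_ed)^2
      + w2/2 (p_cl_m - p_cl)^2
    """
    if simulated.p_ed is None:
        raise ValueError("simulated features must carry p_ed")
    w0, w1, w2 = w.omega
    r = (measured.p_peak - simulated.p_peak,
         measured.p_op - simulated.p_ed,
         measured.p_cl - simulated.p_cl)
    if not all(np.isfinite(r)):
        raise ValueError("non-finite residuals")
    return 0.5 * (w0 * r[0] ** 2 + w1 * r[1] ** 2 + w2 * r[2] ** 2)


def constraint_violations(params: Wk3Params | tuple[float, float, float],
                          metrics: CycleMetrics, simulated: PressureFeatures,
                          b: ConstraintBounds) -> np.ndarray:
    """Signed slack g_k of each inequality written in g <= 0 form."""
    if isinstance(params, Wk3Params):
        Z, R, C = params.Z, params.R, params.C
    else:
        Z, R, C = params
    ratio = R * C / metrics.T_dias
    return np.array([
        1.0 - Z,                             # 1 <= Z
        1.0 - C,                             # 1 <= C
        C - R,                               # C <= R
        b.b0 - ratio,                        # b0 <= RC/T_dias
        ratio - b.b1,                        # RC/T_dias <= b1
        b.b2 - simulated.p_cl / metrics.MAP,  # b2 <= p_cl/MAP
        b.b3 - simulated.p_cl,               # b3 <= p_cl
    ])


def penalty(params: Wk3Params | tuple[float, float, float], metrics: CycleMetrics,
            simulated: PressureFeatures, b: ConstraintBounds) -> float:
    """Quadratic max-penalty kappa * sum(max(0, g_k)^2); zero iff feasible."""
    g = constraint_violations(params, metrics, simulated, b)
    viol = np.clip(g, 0.0, None)
    return float(b.kappa * np.sum(viol * viol))


class Wk3Objective:
    """Total objective (cost + penalty) for one case, optimized for refits.

    Precomputes everything that depends only on the flow trace — the solver
    grid, the ejection window, stroke volume and diastolic duration — so that
    evaluating a new parameter triple costs one linear-recurrence solve plus a
    handful of array reductions.
    """

    def __init__(self, q: HaemoTrace, measured: PressureFeatures,
                 weights: CostWeights | None = None,
                 bounds: ConstraintBounds | None = None,
                 step: float = DEFAULT_STEP_MS) -> None:
        self.measured = measured
        self.weights = weights if weights is not None else CostWeights.from_measured(measured)
        self.bounds = bounds if bounds is not None else ConstraintBounds()
        self.grid = FlowGrid(q, step=step)
        t_on, _, t_cl = ejection_times(q)  # on the original samples: grid-independent
        t0 = float(q.t[0])
        self.T_cycle = float(self.grid.t[-1] - self.grid.t[0])
        self.t_onset = t_on - t0
        self.t_cl = t_cl - t0
        self.T_dias = self.T_cycle - (self.t_cl - self.t_onset)
        h = self.grid.h
        # fractional grid positions of onset (anchor) and valve closure
        self._i_on = min(int(self.t_onset / h), self.grid.t.size - 2)
        self._w_on = self.t_onset / h - self._i_on
        self._i_cl = min(int(self.t_cl / h), self.grid.t.size - 2)
        self._w_cl = self.t_cl / h - self._i_cl
        self.SV = float(np.trapezoid(self.grid.q_node, self.grid.t))
        self.q_peak = float(np.max(self.grid.q_node))
        self._h = self.grid.h

    def simulate(self, params: Wk3Params | tuple[float, float, float]) -> np.ndarray:
        """Pressure on the solver grid anchored at the measured p_op.

        The measured valve-opening pressure is attached at the detected
        ejection-onset sample (the time at which it was extracted), and the
        linear recurrence is inverted over the few pre-onset steps to recover
        the consistent p(0).  When onset falls on the first sample this
        reduces to the plain initial condition p(0) = p_op.
        """
        if isinstance(params, Wk3Params):
            params = (params.Z, params.R, params.C)
        A, B = self.grid.step_coeffs(params)
        return self.grid.propagate(A, B, self._anchored_p0(A, B))

    def _anchored_p0(self, A: float, B: np.ndarray) -> float:
        i, w = self._i_on, self._w_on
        if i == 0 and w == 0.0:
            return self.measured.p_op
        b_pre = 0.0
        for k in range(i):
            b_pre = A * b_pre + B[k]
        # p(t_on) = ((1-w) + w*A) * p_i + w * B_i with p_i = A^i p0 + b_pre
        c = (1.0 - w) + w * A
        return (self.measured.p_op - w * B[i] - c * b_pre) / (c * A**i)

    def _p_cl(self, p: np.ndarray) -> float:
        i, w = self._i_cl, self._w_cl
        return float((1.0 - w) * p[i] + w * p[i + 1])

    def simulated_features(self, params) -> tuple[PressureFeatures, CycleMetrics]:
        p = self.simulate(params)
        feats = PressureFeatures(p_op=float(p[0]), p_peak=float(np.max(p)),
                                 p_cl=self._p_cl(p), p_ed=float(p[-1]))
        metrics = CycleMetrics(
            T_cycle=self.T_cycle, T_dias=self.T_dias,
            MAP=float(np.trapezoid(p, dx=self._h)) / self.T_cycle,
            SV=self.SV, q_peak=self.q_peak, t_cl=self.t_cl, t_onset=self.t_onset)
        return feats, metrics

    def cost_value(self, params) -> float:
        feats, _ = self.simulated_features(params)
        return cost(self.measured, feats, self.weights)

    def penalty_value(self, params) -> float:
        feats, metrics = self.simulated_features(params)
        return penalty(params, metrics, feats, self.bounds)

    def __call__(self, params) -> float:
        """cost + penalty, fast path used by the optimizer."""
        if isinstance(params, Wk3Params):
            Z, R, C = params.Z, params.R, params.C
        else:
            Z, R, C = params
        A, B = self.grid.step_coeffs((Z, R, C))
        p = self.grid.propagate(A, B, self._anchored_p0(A, B))
        p_peak = float(np.max(p))
        p_cl = self._p_cl(p)
        p_ed = float(p[-1])
        map_ = float(np.trapezoid(p, dx=self._h)) / self.T_cycle
        w0, w1, w2 = self.weights.omega
        m = self.measured
        j = 0.5 * (w0 * (m.p_peak - p_peak) ** 2
                   + w1 * (m.p_op - p_ed) ** 2
                   + w2 * (m.p_cl - p_cl) ** 2)
        b = self.bounds
        ratio = R * C / self.T_dias
        g = (1.0 - Z, 1.0 - C, C - R, b.b0 - ratio, ratio - b.b1,
             b.b2 - p_cl / map_, b.b3 - p_cl)
        pen = b.kappa * sum(v * v for v in g if v > 0.0)
        return j + pen


def total_objective(params: Wk3Params, q: HaemoTrace, measured: PressureFeatures,
                    w: CostWeights | None = None, b: ConstraintBounds | None = None,
                    step: float = DEFAULT_STEP_MS) -> float:
    """Convenience wrapper: build the objective for one case and evaluate it."""
    return Wk3Objective(q, measured, weights=w, bounds=b, step=step)(params)
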