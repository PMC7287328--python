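"""Model/Results interface for Wk3 afterload personalization.

`Wk3Model` bundles the data of one case — an aortic flow trace plus the
measured pressure triple — with the fitting configuration; `fit()` returns a
`Wk3Results` object carrying the identified parameters, diagnostics, a
`summary()` table, and simulation, plotting and sensitivity methods.

Example
-------
>>> from afterfit import Wk3Model
>>> from afterfit.synthetic import default_as_case
>>> case = default_as_case()
>>> res = Wk3Model(case.q, case.measured).fit(seed=1)
>>> print(res.summary())            # doctest: +SKIP
"""
from __future__ import annotations

import numpy as np

from .features import (CuffRecord, PressureFeatures, estimate_from_cuff,
                       extract_features, preprocess_traces)
from .objective import (ConstraintBounds, CostWeights, Wk3Objective,
                        constraint_violations)
from .optimize import FitResult, SearchBox, fit_wk3, multistart_uniqueness
from .sensitivity import (SensitivityConfig, SensitivityReport, iv_sweep,
                          sobol_sensitivity)
from .traces import HaemoTrace
from .wk3 import DEFAULT_STEP_MS, Wk3Params


class Wk3Model:
    """Three-element Windkessel afterload model for one cardiac cycle.

    Parameters
    ----------
    flow : aortic flow trace (ml/ms) over one cycle.
    measured : measured pressure triple {p_op, p_peak, p_cl} in kPa.
    weights : cost weights; default makes each term a relative error against
        the measured values.
    bounds : physiological constraint bounds and penalty scale.
    box : search box for {Z, R, C}.
    step : ODE solver step in ms.
    """

    def __init__(self, flow: HaemoTrace, measured: PressureFeatures,
                 weights: CostWeights | None = None,
                 bounds: ConstraintBounds | None = None,
                 box: SearchBox | None = None,
                 step: float = DEFAULT_STEP_MS) -> None:
        self.flow = flow
        self.measured = measured
        self.weights = weights if weights is not None else CostWeights.from_measured(measured)
        self.bounds = bounds if bounds is not None else ConstraintBounds()
        self.box = box if box is not None else SearchBox()
        self.step = step
        self._objective = Wk3Objective(flow, measured, weights=self.weights,
                                       bounds=self.bounds, step=step)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_traces(cls, pressure: HaemoTrace, flow: HaemoTrace,
                    target_T_cycle: float | None = None, **kwargs) -> "Wk3Model":
        """Build from a measured pressure/flow trace pair.

        The traces are synchronized (and optionally rescaled to
        ``target_T_cycle``) and the pressure triple is extracted from them.
        """
        target = target_T_cycle if target_T_cycle is not None else pressure.duration
        p, q = preprocess_traces(pressure, flow, target)
        measured, _ = extract_features(p, q)
        return cls(q, measured, **kwargs)

    @classmethod
    def from_cuff(cls, flow: HaemoTrace, cuff: CuffRecord,
                  fraction_cl: float = 0.7, **kwargs) -> "Wk3Model":
        """Build non-invasively from cuff pressures and an echo gradient."""
        est = estimate_from_cuff(cuff, fraction_cl)
        return cls(flow, est.features, **kwargs)

    # -- fitting ------------------------------------------------------------
    @property
    def objective(self) -> Wk3Objective:
        return self._objective

    def fit(self, seed: int = 0, n_global: int = 256, n_refine: int = 8) -> "Wk3Results":
        """Global-local identification of {Z, R, C}; deterministic per seed."""
        res = fit_wk3(self.flow, self.measured, w=self.weights, b=self.bounds,
                      box=self.box, seed=seed, n_global=n_global,
                      n_refine=n_refine, step=self.step)
        return Wk3Results(self, res)


class Wk3Results:
    """Fit outcome: identified parameters, diagnostics and derived analyses."""

    def __init__(self, model: Wk3Model, fit_result: FitResult) -> None:
        self.model = model
        self.fit_result = fit_result

    # -- estimates ----------------------------------------------------------
    @property
    def params(self) -> Wk3Params:
        return self.fit_result.params

    @property
    def objective_value(self) -> float:
        return self.fit_result.objective_value

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def tau(self) -> float:
        """Diastolic time constant R*C in ms."""
        return self.params.tau

    # -- diagnostics --------------------------------------------------------
    def simulate(self) -> HaemoTrace:
        """Aortic pressure trace at the identified parameters."""
        obj = self.model.objective
        return HaemoTrace(obj.grid.t, obj.simulate(self.params), "kPa")

    def simulated_features(self) -> PressureFeatures:
        feats, _ = self.model.objective.simulated_features(self.params)
        return feats

    def constraint_slacks(self) -> dict[str, float]:
        """Slack (>= 0 means satisfied) of each physiological inequality."""
        feats, metrics = self.model.objective.simulated_features(self.params)
        g = constraint_violations(self.params, metrics, feats, self.model.bounds)
        names = ("Z>=1", "C>=1", "C<=R", "RC/T_dias>=b0", "RC/T_dias<=b1",
                 "p_cl/MAP>=b2", "p_cl>=b3")
        return {name: float(-gi) for name, gi in zip(names, g)}

    def residuals(self) -> dict[str, float]:
        m = self.model.measured
        s = self.simulated_features()
        return {"p_peak": m.p_peak - s.p_peak,
                "p_op_vs_p_ed": m.p_op - (s.p_ed if s.p_ed is not None else np.nan),
                "p_cl": m.p_cl - s.p_cl}

    def summary(self) -> str:
        """Human-readable fit report."""
        p = self.params
        m = self.model.measured
        s = self.simulated_features()
        fr = self.fit_result
        lines = [
            "Wk3 afterload fit",
            "=" * 54,
            f"{'Z  (char. impedance)':34s} {p.Z:10.3f} kPa ms/ml",
            f"{'R  (arterial resistance)':34s} {p.R:10.3f} kPa ms/ml",
            f"{'C  (arterial compliance)':34s} {p.C:10.3f} ml/kPa",
            f"{'tau = R*C':34s} {p.tau:10.2f} ms",
            "-" * 54,
            f"{'objective value':34s} {fr.objective_value:10.3e}",
            f"{'converged / feasible':34s} {str(fr.converged):>10s}",
            f"{'distinct local minima':34s} {fr.distinct_minima:10d}",
            f"{'global candidates':34s} {fr.n_global_candidates:10d}",
            f"{'seed':34s} {fr.seed:10d}",
            "-" * 54,
            "feature            measured   simulated",
            f"p_peak (kPa)     {m.p_peak:10.3f}  {s.p_peak:10.3f}",
            f"p_op/p_ed (kPa)  {m.p_op:10.3f}  {s.p_ed:10.3f}",
            f"p_cl (kPa)       {m.p_cl:10.3f}  {s.p_cl:10.3f}",
        ]
        return "\n".join(lines)

    # -- uniqueness & sensitivity ------------------------------------------
    def multistart_uniqueness(self, n_starts: int = 100, seed: int = 0,
                              rel_tol: float = 0.01) -> tuple[FitResult, int]:
        """Re-run the local stage from random starts; see optimize module."""
        return multistart_uniqueness(self.model.flow, self.model.measured,
                                     w=self.model.weights, b=self.model.bounds,
                                     box=self.model.box, n_starts=n_starts,
                                     seed=seed, rel_tol=rel_tol,
                                     step=self.model.step)

    def sensitivity_iv(self, cfg: SensitivityConfig | None = None) -> SensitivityReport:
        return iv_sweep(self.model.measured, self.model.flow, w=self.model.weights,
                        b=self.model.bounds, box=self.model.box, cfg=cfg,
                        reference=self.fit_result)

    def sensitivity_sobol(self, cfg: SensitivityConfig | None = None) -> SensitivityReport:
        return sobol_sensitivity(self.model.measured, self.model.flow,
                                 w=self.model.weights, b=self.model.bounds,
                                 box=self.model.box, cfg=cfg,
                                 reference=self.fit_result)

    # -- plotting -----------------------------------------------------------
    def plot(self, ax=None):
        """Plot the simulated pressure with the measured triple marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        trace = self.simulate()
        obj = self.model.objective
        m = self.model.measured
        ax.plot(trace.t, trace.v, label="simulated p(t)")
        ax.plot([obj.t_onset, np.nan, obj.t_cl],
                [m.p_op, np.nan, m.p_cl], "o", label="measured points")
        ax.axhline(m.p_peak, ls=":", lw=0.8, label="measured peak")
        ax.set_xlabel("t (ms)")
        ax.set_ylabel("p (kPa)")
        ax.legend(frameon=False)
        return ax

    def to_dict(self) -> dict:
        """JSON-ready representation (used by the file report writer)."""
        fr = self.fit_result
        return {
            "params": {"Z": fr.params.Z, "R": fr.params.R, "C": fr.params.C,
                       "tau": fr.params.tau},
            "objective_value": fr.objective_value,
            "converged": fr.converged,
            "distinct_minima": fr.distinct_minima,
            "n_global_candidates": fr.n_global_candidates,
            "n_local_refinements": fr.n_local_refinements,
            "seed": fr.seed,
            "constraint_slacks": self.constraint_slacks(),
            "residuals": self.residuals(),
        }
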