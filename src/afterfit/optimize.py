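"""Global-local identification of the Wk3 parameter triple.

The objective is cheap but non-convex, so identification proceeds in two
stages: a quasi-random (Sobol') global scan of a physiological search box
followed by bounded simplex refinement of the best candidates.  Refined
minima are clustered to detect multimodality; the multistart helper repeats
the local stage from random feasible starts to verify that the minimizer is
unique within the box.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .features import CycleMetrics, PressureFeatures
from .objective import ConstraintBounds, CostWeights, Wk3Objective
from .traces import HaemoTrace
from .wk3 import DEFAULT_STEP_MS, Wk3Params

#: Relative tolerance for clustering refined minima into distinct solutions.
CLUSTER_REL_TOL = 1e-3
#: Penalty value below which an optimum counts as feasible.
FEASIBILITY_TOL = 1e-9


@dataclass(frozen=True)
class SearchBox:
    """Box constraints for {Z, R, C} in kPa ms/ml, kPa ms/ml, ml/kPa.

    The default brackets reported clinical fits with a generous margin while
    respecting the hard constraints Z >= 1 and C >= 1.
    """

    lower: tuple[float, float, float] = (1.0, 10.0, 1.0)
    upper: tuple[float, float, float] = (50.0, 300.0, 100.0)

    def __post_init__(self) -> None:
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        if not np.all(lo < up):
            raise ValueError("each lower bound must be below its upper bound")
        if lo[0] < 1.0 or lo[2] < 1.0:
            raise ValueError("box must respect the hard bounds Z >= 1 and C >= 1")
        if not np.all(np.isfinite(up)):
            raise ValueError("upper bounds must be finite")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.lower, dtype=float)

    @property
    def up(self) -> np.ndarray:
        return np.asarray(self.upper, dtype=float)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lo) and np.all(x <= self.up))

    def project(self, x: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(x, dtype=float), self.lo, self.up)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a global-local identification run."""

    params: Wk3Params
    objective_value: float
    n_global_candidates: int
    n_local_refinements: int
    distinct_minima: int
    converged: bool
    seed: int

    def __post_init__(self) -> None:
        if self.objective_value < 0:
            raise ValueError("objective_value must be non-negative")


def initial_guess(metrics: CycleMetrics, measured: PressureFeatures,
                  box: SearchBox | None = None,
                  diastolic_pressure: HaemoTrace | None = None) -> Wk3Params:
    """Physiology-based starting triple.

    R comes from MAP over cardiac output; C from the diastolic decay constant
    tau = R*C, estimated either from an exponential fit to a diastolic
    pressure segment or from the closing/end-diastolic pressure ratio; Z is
    taken as a small fraction of R.  The guess is projected into the box.
    """
    box = box or SearchBox()
    co = metrics.cardiac_output
    if co <= 0:
        raise ValueError("zero cardiac output")
    r0 = metrics.MAP / co
    if diastolic_pressure is not None:
        # log-linear fit of the decay segment gives tau directly
        t, v = diastolic_pressure.t, diastolic_pressure.v
        slope = np.polyfit(t - t[0], np.log(np.clip(v, 1e-12, None)), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else metrics.T_dias
    else:
        p_end = measured.p_ed if measured.p_ed is not None else measured.p_op
        ratio = max(measured.p_cl / p_end, 1.05)
        tau0 = metrics.T_dias / np.log(ratio)
    x = box.project(np.array([0.05 * r0, r0, tau0 / r0]))
    return Wk3Params(*x)


def _refine_local(objective, x0: np.ndarray, box: SearchBox) -> tuple[np.ndarray, float, bool]:
    """Bounded Nelder-Mead in log10 space, with one restart.

    Log space equalizes the scales of Z (~10), R (~100) and C (~10) and keeps
    all parameters positive; the restart re-inflates the simplex, guarding
    against premature collapse.
    """
    lo, up = np.log10(box.lo), np.log10(box.up)
    bnds = list(zip(lo, up))

    def fun(y: np.ndarray) -> float:
        return objective(10.0 ** y)

    y = np.clip(np.log10(x0), lo, up)
    ok = True
    for _ in range(2):
        res = minimize(fun, y, method="Nelder-Mead", bounds=bnds,
                       options={"xatol": 1e-8, "fatol": 1e-14,
                                "maxiter": 4000, "maxfev": 8000})
        y = res.x
        ok = bool(res.success)
    return 10.0 ** y, float(res.fun), ok


def _cluster(points: np.ndarray, values: np.ndarray,
             rel_tol: float = CLUSTER_REL_TOL) -> tuple[list[int], np.ndarray]:
    """Greedy clustering by maximum per-parameter relative distance.

    Returns representative indices (best value first) and the cluster label
    of every point.
    """
    order = np.argsort(values, kind="stable")
    reps: list[int] = []
    labels = np.full(points.shape[0], -1)
    for i in order:
        for k, r in enumerate(reps):
            if np.max(np.abs(points[i] - points[r]) / np.abs(points[r])) <= rel_tol:
                labels[i] = k
                break
        else:
            labels[i] = len(reps)
            reps.append(int(i))
    return reps, labels


def _best_with_tiebreak(points: np.ndarray, values: np.ndarray) -> int:
    """Index of the lowest objective; near-ties broken by smallest Z, R, C."""
    vmin = float(np.min(values))
    tol = 1e-9 * max(1.0, abs(vmin))
    cand = np.nonzero(values <= vmin + tol)[0]
    keys = sorted(range(len(cand)), key=lambda j: tuple(points[cand[j]]))
    return int(cand[keys[0]])


def fit_wk3(q: HaemoTrace, measured: PressureFeatures,
            w: CostWeights | None = None, b: ConstraintBounds | None = None,
            box: SearchBox | None = None, seed: int = 0,
            n_global: int = 256, n_refine: int = 8,
            step: float = DEFAULT_STEP_MS) -> FitResult:
    """Identify {Z, R, C} by quasi-random global scan plus local refinement.

    The global stage evaluates the objective at ``n_global`` scrambled Sobol'
    points of the box plus the physiology-based initial guess; the best
    ``n_refine`` are refined by bounded Nelder-Mead.  Refined minima are
    clustered at 1e-3 relative tolerance and the best representative is
    returned.  Deterministic for a given seed.
    """
    box = box or SearchBox()
    obj = Wk3Objective(q, measured, weights=w, bounds=b, step=step)

    sampler = qmc.Sobol(d=3, scramble=True, seed=seed)
    cand = qmc.scale(sampler.random(n_global), box.lo, box.up)
    # MAP is unknown from the point triple alone; the classic diastolic +
    # one-third pulse-pressure estimate is accurate enough for a starting point.
    map_est = measured.p_op + (measured.p_peak - measured.p_op) / 3.0
    metrics = CycleMetrics(T_cycle=obj.T_cycle, T_dias=obj.T_dias,
                           MAP=map_est, SV=obj.SV,
                           q_peak=obj.q_peak, t_cl=obj.t_cl, t_onset=obj.t_onset)
    try:
        guess = initial_guess(metrics, measured, box)
        cand = np.vstack([cand, guess.as_array()])
    except ValueError:
        pass
    vals = np.array([obj(x) for x in cand])
    top = np.argsort(vals, kind="stable")[:n_refine]

    refined, ref_vals, succ = [], [], []
    for i in top:
        x, v, ok = _refine_local(obj, cand[i], box)
        refined.append(x)
        ref_vals.append(v)
        succ.append(ok)
    refined = np.asarray(refined)
    ref_vals = np.asarray(ref_vals)

    reps, _ = _cluster(refined, ref_vals)
    best = _best_with_tiebreak(refined, ref_vals)
    params = Wk3Params(*refined[best])
    pen = obj.penalty_value(params)
    return FitResult(params=params, objective_value=float(ref_vals[best]),
                     n_global_candidates=int(cand.shape[0]),
                     n_local_refinements=len(refined),
                     distinct_minima=len(reps),
                     converged=bool(succ[best] and pen <= FEASIBILITY_TOL),
                     seed=seed)


def refine_from(q: HaemoTrace, measured: PressureFeatures, start: Wk3Params,
                w: CostWeights | None = None, b: ConstraintBounds | None = None,
                box: SearchBox | None = None,
                step: float = DEFAULT_STEP_MS) -> FitResult:
    """Local-only refinement from a given start (warm-started refit)."""
    box = box or SearchBox()
    obj = Wk3Objective(q, measured, weights=w, bounds=b, step=step)
    x, v, ok = _refine_local(obj, start.as_array(), box)
    params = Wk3Params(*x)
    pen = obj.penalty_value(params)
    return FitResult(params=params, objective_value=v, n_global_candidates=0,
                     n_local_refinements=1, distinct_minima=1,
                     converged=bool(ok and pen <= FEASIBILITY_TOL), seed=-1)


def _random_feasible_starts(box: SearchBox, bounds: ConstraintBounds, T_dias: float,
                            n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform box samples satisfying the parameter-only inequality groups."""
    out = []
    while len(out) < n:
        x = box.lo + (box.up - box.lo) * rng.random(3)
        z, r, c = x
        ratio = r * c / T_dias
        if z >= 1 and 1 <= c <= r and bounds.b0 <= ratio <= bounds.b1:
            out.append(x)
    return np.asarray(out)


def multistart_uniqueness(q: HaemoTrace, measured: PressureFeatures,
                          w: CostWeights | None = None,
                          b: ConstraintBounds | None = None,
                          box: SearchBox | None = None,
                          n_starts: int = 100, seed: int = 0,
                          rel_tol: float = 0.01,
                          step: float = DEFAULT_STEP_MS) -> tuple[FitResult, int]:
    """Verify uniqueness of the minimizer by many random local refinements.

    Runs the local stage from ``n_starts`` uniform random feasible points of
    the box and reports the consensus (best) minimizer together with the
    number of starts whose refined triple agrees with it within ``rel_tol``
    relative on every parameter.
    """
    if n_starts < 2:
        raise ValueError("n_starts must be at least 2")
    box = box or SearchBox()
    bounds = b if b is not None else ConstraintBounds()
    obj = Wk3Objective(q, measured, weights=w, bounds=bounds, step=step)
    rng = np.random.default_rng(seed)
    starts = _random_feasible_starts(box, bounds, obj.T_dias, n_starts, rng)

    refined = np.empty((n_starts, 3))
    vals = np.empty(n_starts)
    ok = np.empty(n_starts, dtype=bool)
    for i, x0 in enumerate(starts):
        refined[i], vals[i], ok[i] = _refine_local(obj, x0, box)

    reps, _ = _cluster(refined, vals)
    best = _best_with_tiebreak(refined, vals)
    consensus = refined[best]
    agree = np.max(np.abs(refined - consensus) / np.abs(consensus), axis=1) <= rel_tol
    params = Wk3Params(*consensus)
    pen = obj.penalty_value(params)
    result = FitResult(params=params, objective_value=float(vals[best]),
                       n_global_candidates=n_starts, n_local_refinements=n_starts,
                       distinct_minima=len(reps),
                       converged=bool(ok[best] and pen <= FEASIBILITY_TOL),
                       seed=seed)
    return result, int(np.count_nonzero(agree))
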