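"""Synthetic single-cycle cases with known ground-truth Wk3 parameters.

The generator emulates one cardiac cycle of aortic flow — zero in diastole, a
smooth positive ejection pulse with prescribed stroke volume, ejection time
and cycle length — and the corresponding Wk3 pressure response, so every
fitting and sensitivity routine can be exercised without clinical data.

The default case is "AS-like": it uses a published aortic-stenosis operating
point (Z = 9.26, R = 97.46 kPa ms/ml, C = 8.42 ml/kPa, p_op = 10.0 kPa) with
a half-sine ejection pulse of 80 ml stroke volume over 300 ms in an 800 ms
cycle.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import CycleMetrics, PressureFeatures, extract_features
from .objective import ConstraintBounds, constraint_violations
from .traces import HaemoTrace
from .wk3 import DEFAULT_STEP_MS, Wk3Params, periodic_initial_pressure, solve_wk3

#: Published AS operating point used as the default fixture truth.
AS_PARAMS = Wk3Params(Z=9.26, R=97.46, C=8.42)
#: Published CoA operating point.
COA_PARAMS = Wk3Params(Z=12.75, R=80.40, C=38.66)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic cardiac cycle.

    noise_sd is the standard deviation (kPa) of Gaussian noise added to the
    measured point-pressure triple; trace_noise_rel adds relative Gaussian
    noise to the sampled traces.
    """

    T_cycle: float = 800.0   # ms
    T_ej: float = 300.0      # ms
    SV: float = 80.0         # ml
    params: Wk3Params = field(default_factory=lambda: AS_PARAMS)
    p_op: float = 10.0       # kPa
    EDV: float = 150.0       # ml
    noise_sd: float = 0.0    # kPa, absolute, on point pressures
    noise_rel: float = 0.0   # relative, on point pressures
    trace_noise_rel: float = 0.0
    seed: int = 0
    n_samples: int = 801
    pulse: str = "halfsine"  # or "trapezoid"

    def __post_init__(self) -> None:
        if not 0 < self.T_ej < self.T_cycle:
            raise ValueError("need 0 < T_ej < T_cycle")
        if self.SV <= 0:
            raise ValueError("SV must be positive")
        if self.noise_sd < 0 or self.noise_rel < 0 or self.trace_noise_rel < 0:
            raise ValueError("noise levels must be non-negative")
        if self.pulse not in ("halfsine", "trapezoid"):
            raise ValueError("pulse must be 'halfsine' or 'trapezoid'")


@dataclass(frozen=True)
class SynthCase:
    """A generated case: traces, measured features, metrics and the truth."""

    q: HaemoTrace
    p: HaemoTrace
    V: HaemoTrace
    measured: PressureFeatures
    metrics: CycleMetrics
    truth: Wk3Params
    spec: SynthSpec


def make_flow(spec: SynthSpec) -> HaemoTrace:
    """Deterministic single-cycle ejection pulse with exact stroke volume.

    Half-sine: q(t) = (pi*SV)/(2*T_ej) * sin(pi t/T_ej) on [0, T_ej], zero in
    diastole, so the analytic integral equals SV.  The trapezoid variant ramps
    over T_ej/4 at each end with the plateau height chosen to integrate to SV.
    """
    t = np.linspace(0.0, spec.T_cycle, spec.n_samples)
    q = np.zeros_like(t)
    ej = t <= spec.T_ej
    if spec.pulse == "halfsine":
        q[ej] = (np.pi * spec.SV) / (2.0 * spec.T_ej) * np.sin(np.pi * t[ej] / spec.T_ej)
    else:
        ramp = spec.T_ej / 4.0
        height = spec.SV / (spec.T_ej - ramp)  # area of the trapezoid = SV
        te = t[ej]
        q[ej] = height * np.minimum(1.0, np.minimum(te / ramp, (spec.T_ej - te) / ramp))
    q[q < 0] = 0.0
    return HaemoTrace(t, q, "ml/ms")


def make_case(spec: SynthSpec, *, periodic: bool = False,
              step: float = DEFAULT_STEP_MS) -> SynthCase:
    """Generate flow, Wk3 pressure, volume and measured features for a spec.

    With ``periodic=True`` the initial pressure is solved so that
    p(T_cycle) = p(0), making the measured triple exactly consistent with the
    truth parameters (the clean setting for parameter-recovery experiments);
    otherwise the prescribed p_op is used as p(0), as for the default
    published fixture.
    """
    rng = np.random.default_rng(spec.seed)
    q = make_flow(spec)
    p0 = periodic_initial_pressure(q, spec.params, step=step) if periodic else spec.p_op
    p = solve_wk3(q, spec.params, p0, step=step)

    # LV volume consistent with the flow: V(t) = EDV - integral of q
    cum = np.concatenate([[0.0], np.cumsum(np.diff(q.t) * (q.v[1:] + q.v[:-1]) / 2.0)])
    V = HaemoTrace(q.t, spec.EDV - cum, "ml")

    if spec.trace_noise_rel > 0:
        p = HaemoTrace(p.t, p.v * (1 + spec.trace_noise_rel * rng.standard_normal(p.n)), "kPa")
        q = HaemoTrace(q.t, q.v + spec.trace_noise_rel * np.max(q.v)
                       * rng.standard_normal(q.n), "ml/ms")

    measured, metrics = extract_features(p, q)
    if spec.noise_sd > 0 or spec.noise_rel > 0:
        measured = measured.with_noise(rng, sd=spec.noise_sd, rel=spec.noise_rel)
    return SynthCase(q=q, p=p, V=V, measured=measured, metrics=metrics,
                     truth=spec.params, spec=spec)


def default_as_case(noise_sd: float = 0.0, seed: int = 0) -> SynthCase:
    """The default AS-like fixture at the published operating point."""
    return make_case(SynthSpec(noise_sd=noise_sd, seed=seed))


def random_cases(n: int, seed: int = 0, *, noise_sd: float = 0.0,
                 noise_rel: float = 0.0,
                 bounds: ConstraintBounds | None = None) -> list[SynthCase]:
    """Feasible random periodic cases for recovery experiments.

    Parameter triples are drawn log-uniformly inside the interior of the
    default search box and rejected unless the generated case satisfies every
    physiological inequality group, so all ground truths are attainable by a
    feasible fit.
    """
    bounds = bounds or ConstraintBounds()
    rng = np.random.default_rng(seed)
    cases: list[SynthCase] = []
    while len(cases) < n:
        z = 10.0 ** rng.uniform(np.log10(2.0), np.log10(25.0))
        r = 10.0 ** rng.uniform(np.log10(40.0), np.log10(250.0))
        c = 10.0 ** rng.uniform(np.log10(2.0), np.log10(60.0))
        if not 1 <= c <= r:
            continue
        sv = rng.uniform(55.0, 110.0)
        t_ej = rng.uniform(250.0, 350.0)
        t_cycle = rng.uniform(700.0, 1000.0)
        spec = SynthSpec(T_cycle=t_cycle, T_ej=t_ej, SV=sv,
                         params=Wk3Params(z, r, c),
                         seed=int(rng.integers(2**31 - 1)), noise_sd=noise_sd,
                         noise_rel=noise_rel)
        try:
            case = make_case(spec, periodic=True)
        except ValueError:
            continue
        sim_feats, _ = extract_features(case.p, case.q)
        g = constraint_violations(case.truth, case.metrics, sim_feats, bounds)
        if np.all(g <= 0):
            cases.append(case)
    return cases
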