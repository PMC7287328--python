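"""Propagation of pressure-measurement uncertainty into fitted Wk3 parameters.

Two complementary analyses are provided:

* independent variation (IV): each input pressure in {p_op, p_peak, p_cl} is
  swept one at a time over an even grid of +/- rel_range around its measured
  value, the model is refitted at every grid point, and the extreme signed
  relative deviations of each fitted parameter are reported in percent;
* global variance-based analysis: Saltelli's extension of the Sobol' sequence
  samples the three-input hypercube jointly, the model is refitted per row,
  and first-order Sobol' indices attribute the output variance of each of
  Z, R, C to the individual inputs.

The Saltelli sampling scheme and the first-order estimator are implemented
here on top of scipy's Sobol' sequence generator; an independent multivariate
normal density (variance sigma2 per component, centred on the measured
values) is attached to every sample as a plausibility weight.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .features import PressureFeatures
from .objective import ConstraintBounds, CostWeights
from .optimize import FitResult, SearchBox, fit_wk3, refine_from
from .traces import HaemoTrace
from .wk3 import Wk3Params

INPUT_NAMES = ("p_op", "p_peak", "p_cl")
OUTPUT_NAMES = ("Z", "R", "C")

#: Base sample count matching the full-scale study configuration.
FULL_SCALE_N_SOBOL = 5000


@dataclass(frozen=True)
class SensitivityConfig:
    """Sampling configuration for both sensitivity branches.

    rel_range : relative half-width of input variation (0.10 = +/-10%).
    n_iv : grid points per input in the IV sweep (endpoints and base included).
    n_sobol : base sample count of the Saltelli scheme; the desk-scale default
        is 256, with FULL_SCALE_N_SOBOL restoring the full-scale setting.
    sigma2 : per-component variance (kPa^2) of the normal density weighting.
    refit : "warm" re-optimizes locally from the reference optimum (the
        input-to-parameter mapping is continuous); "full" reruns the complete
        global-local fit per sample.
    """

    rel_range: float = 0.10
    n_iv: int = 100
    n_sobol: int = 256
    sigma2: float = 0.2
    seed: int = 0
    n_bootstrap: int = 200
    refit: str = "warm"

    def __post_init__(self) -> None:
        if not 0 < self.rel_range < 1:
            raise ValueError("rel_range must lie in (0, 1)")
        if self.n_iv < 2 or self.n_sobol < 8:
            raise ValueError("need n_iv >= 2 and n_sobol >= 8")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.refit not in ("warm", "full"):
            raise ValueError("refit must be 'warm' or 'full'")


@dataclass(frozen=True)
class SensitivityReport:
    """Results of one or both sensitivity branches.

    iv_max_pos / iv_max_neg : per (input, output) extreme signed relative
        deviations in percent (IV branch; None if not run).
    sobol_first_order / sobol_conf : first-order indices and bootstrap 95%
        confidence half-widths per (input, output) (Sobol branch; None if not
        run).
    samples : tidy table of inputs, fitted parameters and normal-density
        weights for every evaluated sample.
    """

    config: SensitivityConfig
    reference: FitResult
    iv_max_pos: pd.DataFrame | None = None
    iv_max_neg: pd.DataFrame | None = None
    sobol_first_order: pd.DataFrame | None = None
    sobol_conf: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    n_failed: int = 0


# ---------------------------------------------------------------------------
# Saltelli sampling and first-order Sobol' estimation (generic)
# ---------------------------------------------------------------------------

def saltelli_sample(n: int, lower: np.ndarray, upper: np.ndarray,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Saltelli sample matrices A, B and AB_i over a box.

    A scrambled Sobol' sequence of dimension 2d provides the paired base
    matrices; AB_i equals A with column i replaced from B.  Returns arrays of
    shapes (n, d), (n, d) and (d, n, d); model cost is n*(d+2) evaluations.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    base = qmc.Sobol(d=2 * d, scramble=True, seed=seed).random(n)
    A = lower + (upper - lower) * base[:, :d]
    B = lower + (upper - lower) * base[:, d:]
    AB = np.empty((d, n, d))
    for i in range(d):
        AB[i] = A
        AB[i, :, i] = B[:, i]
    return A, B, AB


def first_order_indices(fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray) -> np.ndarray:
    """First-order Sobol' indices from paired-matrix model evaluations.

    Uses the estimator S_i = mean(fB * (fAB_i - fA)) / Var(concat(fA, fB)).
    fA, fB have shape (n,), fAB shape (d, n).
    """
    y = np.concatenate([fA, fB])
    var = np.var(y)
    if var == 0:
        return np.zeros(fAB.shape[0])
    return np.mean(fB[None, :] * (fAB - fA[None, :]), axis=1) / var


def sobol_first_order(func: Callable[[np.ndarray], np.ndarray],
                      lower, upper, n: int, seed: int = 0,
                      n_bootstrap: int = 0
                      ) -> tuple[np.ndarray, np.ndarray | None]:
    """Estimate first-order indices of ``func`` over a box.

    ``func`` maps an (m, d) array of input rows to (m,) outputs.  Returns the
    index vector and, if ``n_bootstrap`` > 0, bootstrap 95% confidence
    half-widths.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    A, B, AB = saltelli_sample(n, lower, upper, seed=seed)
    fA = np.asarray(func(A), dtype=float)
    fB = np.asarray(func(B), dtype=float)
    fAB = np.stack([np.asarray(func(AB[i]), dtype=float) for i in range(lower.size)])
    s = first_order_indices(fA, fB, fAB)
    conf = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_bootstrap, lower.size))
        for k in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            reps[k] = first_order_indices(fA[idx], fB[idx], fAB[:, idx])
        conf = 1.96 * np.std(reps, axis=0, ddof=1)
    return s, conf


# ---------------------------------------------------------------------------
# Wk3-specific sensitivity
# ---------------------------------------------------------------------------

def _normal_weight(x: np.ndarray, mean: np.ndarray, sigma2: float) -> np.ndarray:
    """Independent multivariate normal density at rows of x."""
    z2 = np.sum((x - mean) ** 2, axis=-1)
    d = mean.size
    return np.exp(-0.5 * z2 / sigma2) / (2 * np.pi * sigma2) ** (d / 2)


class _Refitter:
    """Refits the Wk3 model for perturbed measured triples."""

    def __init__(self, q: HaemoTrace, w, b, box, cfg: SensitivityConfig,
                 reference: FitResult) -> None:
        self.q, self.w, self.b = q, w, b
        self.box = box or SearchBox()
        self.cfg = cfg
        self.reference = reference

    def __call__(self, triple: np.ndarray, base: PressureFeatures) -> np.ndarray:
        measured = replace(base, p_op=float(triple[0]), p_peak=float(triple[1]),
                           p_cl=float(triple[2]))
        if self.cfg.refit == "warm":
            res = refine_from(self.q, measured, self.reference.params,
                              w=self.w, b=self.b, box=self.box)
        else:
            res = fit_wk3(self.q, measured, w=self.w, b=self.b, box=self.box,
                          seed=self.cfg.seed)
        return res.params.as_array()


def _reference_fit(q, base_measured, w, b, box, cfg) -> FitResult:
    return fit_wk3(q, base_measured, w=w, b=b, box=box or SearchBox(), seed=cfg.seed)


def iv_sweep(base_measured: PressureFeatures, q: HaemoTrace,
             w: CostWeights | None = None, b: ConstraintBounds | None = None,
             box: SearchBox | None = None,
             cfg: SensitivityConfig | None = None,
             reference: FitResult | None = None) -> SensitivityReport:
    """One-at-a-time sweep of each input pressure over +/- rel_range.

    Each input is varied on an even grid (endpoints and the base point
    included) while the other two stay fixed; the Wk3 fit is repeated at
    every grid point and the extreme signed relative deviations of Z, R, C
    from the reference fit are reported in percent.
    """
    cfg = cfg or SensitivityConfig()
    if reference is None:
        reference = _reference_fit(q, base_measured, w, b, box, cfg)
    ref = reference.params.as_array()
    refit = _Refitter(q, w, b, box, cfg, reference)

    base = np.array([base_measured.p_op, base_measured.p_peak, base_measured.p_cl])
    factors = np.linspace(1 - cfg.rel_range, 1 + cfg.rel_range, cfg.n_iv)
    if not np.any(np.isclose(factors, 1.0)):
        factors = np.sort(np.append(factors, 1.0))

    max_pos = np.zeros((3, 3))
    max_neg = np.zeros((3, 3))
    rows = []
    n_failed = 0
    for i, name in enumerate(INPUT_NAMES):
        for f in factors:
            triple = base.copy()
            triple[i] = base[i] * f
            try:
                fitted = refit(triple, base_measured)
            except (ValueError, FloatingPointError):
                n_failed += 1
                rows.append(dict(input_varied=name, factor=f, failed=True))
                continue
            dev = (fitted - ref) / ref
            max_pos[i] = np.maximum(max_pos[i], dev)
            max_neg[i] = np.minimum(max_neg[i], dev)
            rows.append(dict(input_varied=name, factor=f,
                             p_op=triple[0], p_peak=triple[1], p_cl=triple[2],
                             Z=fitted[0], R=fitted[1], C=fitted[2],
                             weight=float(_normal_weight(triple, base, cfg.sigma2)),
                             failed=False))
    idx = pd.Index(INPUT_NAMES, name="input")
    return SensitivityReport(
        config=cfg, reference=reference,
        iv_max_pos=pd.DataFrame(100 * max_pos, index=idx, columns=OUTPUT_NAMES),
        iv_max_neg=pd.DataFrame(100 * max_neg, index=idx, columns=OUTPUT_NAMES),
        samples=pd.DataFrame(rows), n_failed=n_failed)


def sobol_sensitivity(base_measured: PressureFeatures, q: HaemoTrace,
                      w: CostWeights | None = None,
                      b: ConstraintBounds | None = None,
                      box: SearchBox | None = None,
                      cfg: SensitivityConfig | None = None,
                      reference: FitResult | None = None) -> SensitivityReport:
    """First-order Sobol' indices of the fitted Wk3 parameters.

    Saltelli matrices over the +/- rel_range hypercube around the measured
    triple are refitted row by row; indices are estimated per output with
    bootstrap confidence half-widths, and every sample row carries its
    normal-density plausibility weight.
    """
    cfg = cfg or SensitivityConfig()
    if reference is None:
        reference = _reference_fit(q, base_measured, w, b, box, cfg)
    refit = _Refitter(q, w, b, box, cfg, reference)

    base = np.array([base_measured.p_op, base_measured.p_peak, base_measured.p_cl])
    lower = base * (1 - cfg.rel_range)
    upper = base * (1 + cfg.rel_range)
    A, B, AB = saltelli_sample(cfg.n_sobol, lower, upper, seed=cfg.seed)

    n_failed = 0

    def eval_rows(X: np.ndarray) -> np.ndarray:
        nonlocal n_failed
        out = np.empty((X.shape[0], 3))
        for j, row in enumerate(X):
            try:
                out[j] = refit(row, base_measured)
            except (ValueError, FloatingPointError):
                n_failed += 1
                out[j] = np.nan
        return out

    fA, fB = eval_rows(A), eval_rows(B)
    fAB = np.stack([eval_rows(AB[i]) for i in range(3)])  # (d, n, outputs)

    good = (np.all(np.isfinite(fA), axis=1) & np.all(np.isfinite(fB), axis=1)
            & np.all(np.isfinite(fAB), axis=(0, 2)))
    fA, fB, fAB = fA[good], fB[good], fAB[:, good]
    n_good = int(np.count_nonzero(good))
    if n_good < 8:
        raise ValueError("too few successful refits for Sobol estimation")

    rng = np.random.default_rng(cfg.seed)
    S = np.empty((3, 3))
    conf = np.empty((3, 3))
    for k in range(3):  # outputs Z, R, C
        S[:, k] = first_order_indices(fA[:, k], fB[:, k], fAB[:, :, k])
        reps = np.empty((cfg.n_bootstrap, 3))
        for r in range(cfg.n_bootstrap):
            idx = rng.integers(0, n_good, size=n_good)
            reps[r] = first_order_indices(fA[idx, k], fB[idx, k], fAB[:, idx, k])
        conf[:, k] = 1.96 * np.std(reps, axis=0, ddof=1)

    stacked_x = np.vstack([A[good], B[good]])
    stacked_f = np.vstack([fA, fB])
    samples = pd.DataFrame(
        np.hstack([stacked_x, stacked_f,
                   _normal_weight(stacked_x, base, cfg.sigma2)[:, None]]),
        columns=[*INPUT_NAMES, *OUTPUT_NAMES, "weight"])
    idx = pd.Index(INPUT_NAMES, name="input")
    return SensitivityReport(
        config=cfg, reference=reference,
        sobol_first_order=pd.DataFrame(S, index=idx, columns=OUTPUT_NAMES),
        sobol_conf=pd.DataFrame(conf, index=idx, columns=OUTPUT_NAMES),
        samples=samples, n_failed=n_failed)
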