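"""Global-local parameter identification: recovery, uniqueness, feasibility."""
import numpy as np
import pytest

import afterfit as af
from afterfit.objective import Wk3Objective
from afterfit.optimize import refine_from


class TestInitialGuess:
    def test_resistance_from_map_over_co(self):
        metrics = af.CycleMetrics(T_cycle=800.0, T_dias=500.0, MAP=12.0, SV=80.0,
                                  q_peak=0.4, t_cl=300.0)
        measured = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0, p_ed=10.0)
        guess = af.initial_guess(metrics, measured, af.SearchBox(upper=(50, 500, 100)))
        assert guess.R == pytest.approx(12.0 / (80.0 / 800.0))

    def test_within_25pct_of_truth_on_synthetic(self, periodic_case):
        feats, metrics = af.extract_features(periodic_case.p, periodic_case.q)
        guess = af.initial_guess(metrics, feats)
        # R0 approximates R + Z (MAP sees the total series resistance)
        assert abs(guess.R - periodic_case.truth.R) / periodic_case.truth.R < 0.25

    def test_projected_into_box(self):
        metrics = af.CycleMetrics(T_cycle=800.0, T_dias=500.0, MAP=40.0, SV=20.0,
                                  q_peak=0.4, t_cl=300.0)
        measured = af.PressureFeatures(p_op=30.0, p_peak=45.0, p_cl=40.0, p_ed=30.0)
        box = af.SearchBox()
        guess = af.initial_guess(metrics, measured, box)
        assert box.contains(guess.as_array())


class TestFitWk3:
    def test_recovers_known_parameters(self):
        truth = af.Wk3Params(Z=10.0, R=90.0, C=10.0)
        case = af.make_case(af.SynthSpec(params=truth), periodic=True)
        res = af.fit_wk3(case.q, case.measured, seed=3)
        err = np.abs(res.params.as_array() - truth.as_array()) / truth.as_array()
        assert np.all(err < 0.02)
        assert res.converged

    def test_descent_from_optimum(self, periodic_case, as_results):
        res = af.fit_wk3(periodic_case.q, periodic_case.measured, seed=3)
        again = refine_from(periodic_case.q, periodic_case.measured, res.params)
        assert again.objective_value <= res.objective_value + 1e-15

    def test_feasible_optimum(self, as_results):
        slacks = as_results.constraint_slacks()
        assert all(s >= -1e-9 for s in slacks.values())

    def test_reproducible_per_seed(self, as_case):
        r1 = af.fit_wk3(as_case.q, as_case.measured, seed=11)
        r2 = af.fit_wk3(as_case.q, as_case.measured, seed=11)
        assert r1 == r2

    def test_beats_brute_force_grid(self, as_case, as_results):
        # oracle: exhaustive scan of a shrunken box around the optimum
        obj = Wk3Objective(as_case.q, as_case.measured)
        p = as_results.params
        zs = np.linspace(p.Z * 0.7, p.Z * 1.3, 20)
        rs = np.linspace(p.R * 0.7, p.R * 1.3, 20)
        cs = np.linspace(p.C * 0.7, p.C * 1.3, 20)
        grid_min = min(obj((z, r, c)) for z in zs for r in rs for c in cs)
        assert grid_min >= as_results.objective_value - 1e-6

    def test_monotone_improvement_over_global_candidates(self, as_case):
        from scipy.stats import qmc
        box = af.SearchBox()
        obj = Wk3Objective(as_case.q, as_case.measured)
        res = af.fit_wk3(as_case.q, as_case.measured, seed=5)
        cand = qmc.scale(qmc.Sobol(d=3, scramble=True, seed=5).random(256),
                         box.lo, box.up)
        assert res.objective_value <= min(obj(x) for x in cand) + 1e-12


class TestMultistartUniqueness:
    def test_all_starts_concordant_small(self, as_case):
        res, concordant = af.multistart_uniqueness(as_case.q, as_case.measured,
                                                   n_starts=12, seed=4)
        assert concordant == 12
        assert res.distinct_minima == 1

    def test_deterministic(self, as_case):
        a = af.multistart_uniqueness(as_case.q, as_case.measured, n_starts=4, seed=9)
        b = af.multistart_uniqueness(as_case.q, as_case.measured, n_starts=4, seed=9)
        assert a == b

    def test_requires_two_starts(self, as_case):
        with pytest.raises(ValueError):
            af.multistart_uniqueness(as_case.q, as_case.measured, n_starts=1)


class TestParameterRecoverySuite:
    def test_median_recovery_noise_free(self):
        cases = af.random_cases(8, seed=21)
        errs = []
        for c in cases:
            r = af.fit_wk3(c.q, c.measured, seed=2)
            errs.append(np.abs(r.params.as_array() - c.truth.as_array())
                        / c.truth.as_array())
        assert np.all(np.median(errs, axis=0) <= 0.02)
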