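"""Cost functional, penalty terms and the combined objective."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import afterfit as af
from afterfit.objective import Wk3Objective, constraint_violations


def unit_weights():
    return af.CostWeights(gamma=(1.0, 1.0, 1.0), ref_means=(1.0, 1.0, 1.0))


def metrics_for(T_dias=500.0, MAP=12.0):
    return af.CycleMetrics(T_cycle=800.0, T_dias=T_dias, MAP=MAP, SV=80.0,
                           q_peak=0.4, t_cl=300.0)


class TestCost:
    def test_zero_for_perfect_match(self):
        m = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0)
        s = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0, p_ed=10.0)
        assert af.cost(m, s, unit_weights()) == 0.0

    def test_direct_evaluation(self):
        # residuals (peak, periodicity, closing) = (1, 2, 3) kPa
        m = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0)
        s = af.PressureFeatures(p_op=10.0, p_peak=16.0, p_cl=11.0, p_ed=8.0)
        assert af.cost(m, s, unit_weights()) == pytest.approx((1 + 4 + 9) / 2)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_linear_in_weights(self, scale):
        m = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0)
        s = af.PressureFeatures(p_op=10.0, p_peak=16.5, p_cl=13.0, p_ed=9.0)
        w1 = unit_weights()
        w2 = af.CostWeights(gamma=(scale,) * 3, ref_means=(1.0,) * 3)
        assert af.cost(m, s, w2) == pytest.approx(scale * af.cost(m, s, w1))

    def test_missing_p_ed_rejected(self):
        m = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0)
        with pytest.raises(ValueError):
            af.cost(m, m, unit_weights())


class TestPenalty:
    def test_zero_at_published_optimum(self, as_case):
        params = af.Wk3Params(9.26, 97.46, 8.42)
        obj = Wk3Objective(as_case.q, as_case.measured)
        feats, metrics = obj.simulated_features(params)
        assert af.penalty(params, metrics, feats, obj.bounds) == 0.0

    def test_single_active_term(self):
        b = af.ConstraintBounds()
        s = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0, p_ed=9.0)
        val = af.penalty((0.5, 100.0, 10.0), metrics_for(), s, b)
        assert val == pytest.approx(b.kappa * 0.5**2)

    def test_boundary_is_feasible(self):
        b = af.ConstraintBounds()
        s = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0, p_ed=9.0)
        # C = R exactly sits on the boundary of C <= R
        assert af.penalty((5.0, 30.0, 30.0), metrics_for(T_dias=600.0), s, b) == 0.0

    def test_continuous_across_each_boundary(self):
        # quadratic max-penalty is C^1: finite differences stay bounded across g=0
        b = af.ConstraintBounds(kappa=1.0)
        s = af.PressureFeatures(p_op=10.0, p_peak=17.0, p_cl=14.0, p_ed=9.0)
        met = metrics_for()
        for eps in (1e-6, 1e-8):
            lo = af.penalty((1.0 - eps, 100.0, 10.0), met, s, b)
            hi = af.penalty((1.0 + eps, 100.0, 10.0), met, s, b)
            assert abs(hi - lo) < 10 * eps


class TestTotalObjective:
    def test_near_zero_at_generating_parameters(self, periodic_case):
        val = af.total_objective(periodic_case.truth, periodic_case.q,
                                 periodic_case.measured)
        assert val < 1e-10

    def test_constraint_order_invariance(self, as_case):
        obj = Wk3Objective(as_case.q, as_case.measured)
        params = af.Wk3Params(5.0, 60.0, 20.0)
        feats, met = obj.simulated_features(params)
        g = constraint_violations(params, met, feats, obj.bounds)
        total = obj.bounds.kappa * np.sum(np.clip(g, 0, None) ** 2)
        assert obj.penalty_value(params) == pytest.approx(total)

    def test_perturbation_increases_objective(self, periodic_case):
        obj = Wk3Objective(periodic_case.q, periodic_case.measured)
        truth = periodic_case.truth
        bumped = af.Wk3Params(truth.Z * 1.5, truth.R, truth.C)
        assert obj(bumped) > obj(truth)

    def test_deterministic_evaluation(self, as_case):
        obj = Wk3Objective(as_case.q, as_case.measured)
        params = (7.0, 88.0, 12.0)
        assert obj(params) == obj(params)

    def test_nonnegative_everywhere(self, as_case):
        obj = Wk3Objective(as_case.q, as_case.measured)
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.uniform([1, 10, 1], [50, 300, 100])
            assert obj(x) >= 0.0
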