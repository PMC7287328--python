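"""Feature extraction, trace pre-processing and cuff-based estimation."""
import numpy as np
import pytest

import afterfit as af
from afterfit.features import ejection_times


class TestVolumeToFlow:
    def test_linear_volume_gives_constant_flow(self):
        t = np.linspace(0, 100, 101)
        V = af.HaemoTrace(t, 150 - 0.5 * t, "ml")
        q = af.volume_to_flow(V)
        np.testing.assert_allclose(q.v, 0.5, rtol=1e-12)

    def test_constant_volume_gives_zero_flow(self):
        t = np.linspace(0, 100, 101)
        q = af.volume_to_flow(af.HaemoTrace(t, np.full(101, 120.0), "ml"))
        assert np.all(q.v == 0)

    def test_cycle_integral_reproduces_ejected_volume(self, as_case):
        # EDV 150, ESV 70 by construction of the default fixture
        q = af.volume_to_flow(as_case.V)
        sv = q.integral()
        assert sv == pytest.approx(150.0 - 70.0, rel=5e-3)

    def test_flow_clamped_to_zero_in_diastole(self, as_case):
        q = af.volume_to_flow(as_case.V)
        diastole = q.t > as_case.spec.T_ej + 10
        assert np.all(q.v[diastole] == 0)


class TestPreprocessTraces:
    def test_idempotent_on_clean_input(self, as_case):
        p1, q1 = af.preprocess_traces(as_case.p, as_case.q, 800.0)
        p2, q2 = af.preprocess_traces(p1, q1, 800.0)
        np.testing.assert_allclose(p2.v, p1.v, atol=1e-9)
        np.testing.assert_allclose(q2.v, q1.v, atol=1e-9)

    def test_recovers_circular_shift(self, as_case):
        q = as_case.q
        shift = 40.0
        v_shift = np.interp(np.mod(q.t - shift, q.duration), q.t, q.v)
        q_shifted = af.HaemoTrace(q.t, v_shift, "ml/ms")
        _, q_out = af.preprocess_traces(as_case.p, q_shifted, 800.0)
        t_on, _, _ = ejection_times(q_out)
        step = q_out.t[1] - q_out.t[0]
        assert t_on - q_out.t[0] <= step + 1e-9

    def test_time_rescaling_preserves_stroke_volume(self, as_case):
        sv0 = as_case.q.integral()
        p_out, q_out = af.preprocess_traces(as_case.p, as_case.q, 1000.0)
        assert q_out.duration == pytest.approx(1000.0)
        assert q_out.integral() == pytest.approx(sv0, rel=1e-3)
        # pressure amplitude untouched
        assert p_out.v.max() == pytest.approx(as_case.p.v.max(), rel=1e-6)

    def test_incompatible_cycle_lengths_rejected(self, as_case):
        t_short = np.linspace(0, 300, 100)
        q_short = af.HaemoTrace(t_short, np.sin(np.pi * t_short / 300) + 0.1, "ml/ms")
        with pytest.raises(ValueError, match="50%"):
            af.preprocess_traces(as_case.p, q_short, 800.0)

    def test_no_ejection_rejected(self, as_case):
        flat = af.HaemoTrace(as_case.q.t, np.zeros(as_case.q.n), "ml/ms")
        with pytest.raises(ValueError, match="ejection"):
            af.preprocess_traces(as_case.p, flat, 800.0)


class TestExtractFeatures:
    def test_definitions_on_constructed_cycle(self, as_case):
        feats, metrics = af.extract_features(as_case.p, as_case.q)
        assert feats.p_peak == as_case.p.v.max()
        # half-sine flow returns to zero at T_ej
        assert metrics.t_cl == pytest.approx(as_case.spec.T_ej, abs=1.0)
        assert metrics.T_dias == pytest.approx(
            metrics.T_cycle - (metrics.t_cl - metrics.t_onset))
        assert metrics.SV == pytest.approx(as_case.spec.SV, rel=2e-3)
        assert metrics.q_peak == as_case.q.v.max()

    def test_map_of_constant_pressure(self):
        t = np.linspace(0, 800, 801)
        p = af.HaemoTrace(t, np.full(t.size, 12.0), "kPa")
        q = af.make_flow(af.SynthSpec())
        _, metrics = af.extract_features(p, q)
        assert metrics.MAP == pytest.approx(12.0, rel=1e-12)

    def test_published_triple_is_valid_features(self):
        feats = af.PressureFeatures(p_op=10.00, p_cl=15.45, p_peak=17.87)
        assert feats.p_peak >= max(feats.p_op, feats.p_cl)

    def test_ordering_invariants_on_simulated_pressure(self, as_case):
        feats, metrics = af.extract_features(as_case.p, as_case.q)
        assert feats.p_op <= feats.p_peak
        t_peak_p = as_case.p.t[np.argmax(as_case.p.v)]
        assert metrics.t_onset < t_peak_p <= metrics.t_cl


class TestEstimateFromCuff:
    def test_lv_peak_adds_valve_drop(self):
        est = af.estimate_from_cuff(af.CuffRecord(10.0, 17.0, 3.0))
        assert est.p_lv_est == pytest.approx(20.0)
        assert est.features.p_peak == 17.0
        assert est.features.p_op == 10.0

    def test_no_stenosis_keeps_cuff_systolic(self):
        est = af.estimate_from_cuff(af.CuffRecord(10.0, 17.0, 0.0))
        assert est.p_lv_est == 17.0

    def test_closing_pressure_fraction(self):
        est = af.estimate_from_cuff(af.CuffRecord(10.0, 18.0), fraction_cl=0.7)
        assert est.features.p_cl == pytest.approx(15.6)

    def test_inverted_cuff_rejected(self):
        with pytest.raises(ValueError):
            af.CuffRecord(17.0, 10.0)
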