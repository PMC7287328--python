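"""Sensitivity analyses: Sobol' estimator oracles and IV sweep behaviour."""
import numpy as np
import pytest

import afterfit as af
from afterfit.sensitivity import first_order_indices, saltelli_sample


def ishigami(X, a=7.0, b=0.1):
    return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
            + b * X[:, 2] ** 4 * np.sin(X[:, 0]))


def ishigami_first_order(a=7.0, b=0.1):
    # closed-form variance decomposition of the Ishigami function
    v1 = 0.5 * (1 + b * np.pi**4 / 5) ** 2
    v2 = a**2 / 8
    v3 = 0.0
    v_total = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
    return np.array([v1, v2, v3]) / v_total


class TestSobolEstimator:
    def test_single_input_dependence(self):
        s, _ = af.sobol_first_order(lambda X: np.sin(X[:, 0]),
                                    [-1, -1, -1], [1, 1, 1], n=2**10, seed=0)
        assert s[0] == pytest.approx(1.0, abs=0.02)
        assert abs(s[1]) < 0.02 and abs(s[2]) < 0.02

    def test_additive_equal_variance(self):
        s, _ = af.sobol_first_order(lambda X: X.sum(axis=1),
                                    [0, 0, 0], [1, 1, 1], n=2**11, seed=0)
        assert np.allclose(s, 1 / 3, atol=0.02)
        # purely additive: first-order indices sum to one
        assert s.sum() == pytest.approx(1.0, abs=0.03)

    def test_ishigami_against_closed_form(self):
        expected = ishigami_first_order()
        s, conf = af.sobol_first_order(ishigami, [-np.pi] * 3, [np.pi] * 3,
                                       n=2**12, seed=3, n_bootstrap=50)
        assert np.allclose(s, expected, atol=0.04)
        assert conf is not None and np.all(conf > 0)

    def test_stable_across_seeds(self):
        vals = [af.sobol_first_order(ishigami, [-np.pi] * 3, [np.pi] * 3,
                                     n=2**12, seed=seed)[0]
                for seed in (1, 2)]
        assert np.allclose(vals[0], vals[1], atol=0.05)

    def test_saltelli_shapes(self):
        A, B, AB = saltelli_sample(16, [0, 0], [1, 1], seed=0)
        assert A.shape == (16, 2) and B.shape == (16, 2) and AB.shape == (2, 16, 2)
        np.testing.assert_array_equal(AB[0][:, 1], A[:, 1])
        np.testing.assert_array_equal(AB[0][:, 0], B[:, 0])

    def test_zero_variance_function(self):
        fA = np.ones(8)
        assert np.all(first_order_indices(fA, fA, np.ones((2, 8))) == 0)


@pytest.fixture(scope="module")
def iv_report(as_results):
    cfg = af.SensitivityConfig(n_iv=11, n_sobol=64, n_bootstrap=50, seed=1)
    return as_results.sensitivity_iv(cfg)


class TestIVSweep:
    def test_base_point_reproduces_reference(self, iv_report, as_results):
        samples = iv_report.samples
        base_rows = samples[np.isclose(samples["factor"], 1.0)]
        ref = as_results.params.as_array()
        for _, row in base_rows.iterrows():
            fitted = np.array([row["Z"], row["R"], row["C"]])
            assert np.max(np.abs(fitted - ref) / ref) < 1e-6

    def test_impedance_most_resistance_least_sensitive(self, iv_report):
        # under peak-pressure perturbation R barely moves while Z swings hard
        dz = max(iv_report.iv_max_pos.loc["p_peak", "Z"],
                 -iv_report.iv_max_neg.loc["p_peak", "Z"])
        dr = max(iv_report.iv_max_pos.loc["p_peak", "R"],
                 -iv_report.iv_max_neg.loc["p_peak", "R"])
        assert dr < dz

    def test_signed_percent_convention(self, iv_report):
        assert np.all(iv_report.iv_max_pos.to_numpy() >= 0)
        assert np.all(iv_report.iv_max_neg.to_numpy() <= 0)

    def test_spread_shrinks_with_range(self, as_results):
        spreads = []
        for rel in (0.10, 0.05, 0.025):
            cfg = af.SensitivityConfig(rel_range=rel, n_iv=5, seed=1)
            rep = as_results.sensitivity_iv(cfg)
            spreads.append(np.ptp(rep.samples["Z"].to_numpy()))
        assert spreads[0] > spreads[1] > spreads[2]


class TestSobolOnModel:
    def test_indices_within_estimator_bounds(self, as_results):
        cfg = af.SensitivityConfig(n_sobol=64, n_bootstrap=20, seed=1)
        rep = as_results.sensitivity_sobol(cfg)
        s = rep.sobol_first_order.to_numpy()
        assert np.all(s > -0.3) and np.all(s < 1.3)
        assert rep.samples is not None and np.all(rep.samples["weight"] >= 0)
        assert rep.n_failed == 0

    def test_peak_pressure_drives_impedance(self, as_results):
        # mirrors the dominant role of peak pressure for Z
        cfg = af.SensitivityConfig(n_sobol=64, n_bootstrap=20, seed=1)
        rep = as_results.sensitivity_sobol(cfg)
        s = rep.sobol_first_order
        assert s.loc["p_peak", "Z"] > s.loc["p_peak", "R"]


class TestSensitivityConfig:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            af.SensitivityConfig(rel_range=0.0)
        with pytest.raises(ValueError):
            af.SensitivityConfig(n_sobol=4)
        with pytest.raises(ValueError):
            af.SensitivityConfig(refit="adaptive")
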