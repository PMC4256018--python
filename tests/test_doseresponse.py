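import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from ornpn.doseresponse import (
    HillModel,
    LatencyModel,
    derive_characteristics,
    derive_latency_characteristics,
    fit_hill,
    fit_latency_line,
    hill_value,
    latency_value,
)


class TestHillValue:
    def test_half_maximum_at_ed50(self):
        assert hill_value(163.0, 1.35, 0.81, 1.35) == pytest.approx(81.5)

    def test_limits(self):
        assert hill_value(100.0, 0.0, 1.0, 50.0) == pytest.approx(100.0)
        assert hill_value(100.0, 0.0, 1.0, -50.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_point(self):
        # one log unit above ED50 with unit slope: F = 100 / 1.1
        assert hill_value(100.0, 0.0, 1.0, 1.0) == pytest.approx(100.0 / 1.1)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_dose(self, c1, c2):
        f1, f2 = hill_value(100.0, 0.0, 0.8, c1), hill_value(100.0, 0.0, 0.8, c2)
        if c1 < c2:
            assert f1 <= f2
        elif c1 > c2:
            assert f1 >= f2


class TestCharacteristics:
    def test_symmetric_degenerate_case(self):
        # F_M = 2 F_0 is the boundary: characteristics collapse onto ED50
        c0, cs, dc = derive_characteristics(10.0 + 1e-9, 0.5, 1.0, F_0=5.0)
        assert c0 == pytest.approx(0.5, abs=1e-4)
        assert dc == pytest.approx(0.0, abs=1e-3)

    def test_undefined_below_twice_criterion(self):
        assert np.isnan(derive_characteristics(9.0, 0.0, 1.0, 5.0)[2])

    @pytest.mark.parametrize("F_M,n,expected", [(163.0, 0.81, 3.7029),
                                                (62.0, 0.79, 2.6757)])
    def test_dynamic_range_of_typical_neurons(self, F_M, n, expected):
        _, _, dc = derive_characteristics(F_M, 0.0, n, F_0=5.0)
        assert dc == pytest.approx(expected, abs=1e-3)

    def test_closed_form_matches_root_finding(self):
        # independent oracle: solve F(C) = F_0 and F(C) = F_M - F_0 directly
        rng = np.random.default_rng(0)
        for _ in range(100):
            F_M = rng.uniform(20.0, 300.0)
            C_half = rng.uniform(-2.0, 2.0)
            n = rng.uniform(0.3, 3.0)
            c0, cs, dc = derive_characteristics(F_M, C_half, n, F_0=5.0)
            c0_num = brentq(lambda C: hill_value(F_M, C_half, n, C) - 5.0,
                            C_half - 50, C_half + 50, xtol=1e-13)
            cs_num = brentq(lambda C: hill_value(F_M, C_half, n, C) - (F_M - 5.0),
                            C_half - 50, C_half + 50, xtol=1e-13)
            assert c0 == pytest.approx(c0_num, abs=1e-9)
            assert cs == pytest.approx(cs_num, abs=1e-9)
            assert dc == pytest.approx(cs_num - c0_num, abs=1e-9)

    @given(st.floats(0.3, 3.0), st.floats(0.31, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_dynamic_range_decreases_with_hill_slope(self, n1, n2):
        dc1 = derive_characteristics(163.0, 0.0, n1)[2]
        dc2 = derive_characteristics(163.0, 0.0, n2)[2]
        if n1 < n2:
            assert dc1 > dc2


class TestHillFit:
    doses = np.array([-1.0, 0.0, 1.0, 2.0, 3.0, 4.0])

    def test_noiseless_recovery_is_exact(self):
        truth = (163.0, 1.35, 0.81)
        res = fit_hill(self.doses, hill_value(*truth, self.doses))
        assert res.converged
        np.testing.assert_allclose(res.params, truth, atol=1e-6)

    def test_degenerate_data_flagged(self):
        res = fit_hill(self.doses, np.full(6, 50.0))
        assert not res.converged

    def test_noisy_recovery_over_replicates(self):
        # two repeats per dose (the recording protocol for PNs) under
        # multiplicative CV-0.33 noise; the asymptote keeps a mild upward
        # bias (the top doses dominate it), the ED50 is unbiased
        rng = np.random.default_rng(11)
        truth = (163.0, 1.35, 0.81)
        doses = np.repeat(self.doses, 2)
        fm, ch = [], []
        for _ in range(200):
            noisy = hill_value(*truth, doses) * np.clip(
                1 + 0.33 * rng.standard_normal(doses.size), 0.05, None)
            res = fit_hill(doses, noisy)
            fm.append(res.F_M)
            ch.append(res.C_half)
        assert np.median(fm) == pytest.approx(163.0, rel=0.15)
        assert np.median(np.abs(np.array(ch) - 1.35)) < 0.3

    def test_saturating_data_pins_f_max_to_observed_top(self):
        # top two doses within 15% -> F_M close to the observed maximum
        truth = (120.0, 0.0, 1.0)
        res = fit_hill(self.doses, hill_value(*truth, self.doses))
        top = hill_value(*truth, 4.0)
        assert abs(res.F_M - top) / top < 0.15

    def test_summary_contains_characteristics(self):
        res = fit_hill(self.doses, hill_value(163.0, 1.35, 0.81, self.doses))
        text = res.summary()
        assert "C_0" in text and "Delta_C" in text

    def test_standard_errors_finite_for_clean_fit(self):
        rng = np.random.default_rng(5)
        rates = hill_value(163.0, 1.35, 0.81, self.doses) + rng.normal(0, 3, 6)
        res = fit_hill(self.doses, np.clip(rates, 0, None))
        assert np.all(np.isfinite(res.bse))


class TestLatencyFit:
    def test_exact_line_recovery(self):
        doses = np.array([-1.0, 0.0, 1.0])
        res = fit_latency_line(doses, 100.0 - 20.0 * doses)
        assert res.converged
        assert res.L_0 == pytest.approx(100.0, abs=1e-9)
        assert res.lam == pytest.approx(20.0, abs=1e-9)

    def test_floor_prediction(self):
        doses = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        lat = latency_value(100.0, 20.0, 40.0, doses)
        res = fit_latency_line(doses, lat)
        assert res.predict(10.0) == pytest.approx(40.0)
        assert res.L_m == 40.0

    def test_increasing_latency_flagged(self):
        doses = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            res = fit_latency_line(doses, 50.0 + 10.0 * doses)
        assert not res.converged

    def test_noisy_slope_recovery_over_replicates(self):
        rng = np.random.default_rng(3)
        doses = np.array([-1.0, 0.0, 1.0, 2.0, 3.0, 4.0])
        truth = latency_value(150.0, 28.0, 60.0, doses)
        lams = []
        for _ in range(100):
            res = fit_latency_line(doses, truth + rng.normal(0, 10.0, 6))
            if res.converged:
                lams.append(res.lam)
        assert np.median(np.abs(np.array(lams) - 28.0) / 28.0) < 0.15

    def test_floored_points_do_not_attenuate_slope(self):
        doses = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0])
        lat = latency_value(150.0, 28.0, 90.0, doses)  # floor binds from ~2.1
        res = fit_latency_line(doses, lat)
        assert res.lam == pytest.approx(28.0, rel=0.01)


class TestLatencyCharacteristics:
    def test_maximum_latency_formula(self):
        L_M, dL = derive_latency_characteristics(100.0, 20.0, 40.0, C_0=-2.0)
        assert L_M == 140.0 and dL == 100.0

    def test_latency_at_zero_threshold(self):
        L_M, _ = derive_latency_characteristics(100.0, 20.0, 40.0, C_0=0.0)
        assert L_M == 100.0

    def test_missing_threshold_undefined(self):
        L_M, dL = derive_latency_characteristics(100.0, 20.0, 40.0,
                                                 C_0=float("nan"))
        assert np.isnan(L_M) and np.isnan(dL)

    def test_joint_pipeline_matches_closed_form_oracle(self, median_orn):
        doses = np.linspace(-1, 4, 8)
        hill = fit_hill(doses, hill_value(median_orn.F_M, median_orn.C_half,
                                          median_orn.n, doses))
        lat = fit_latency_line(doses, latency_value(
            median_orn.L_0, median_orn.lam, median_orn.L_m, doses))
        L_M, _ = lat.characteristics(hill.C_0)
        c0_true = median_orn.C_half - np.log10(
            median_orn.F_M / 5.0 - 1.0) / median_orn.n
        expected = median_orn.L_0 - median_orn.lam * c0_true
        assert L_M == pytest.approx(expected, abs=2.0)


def test_model_objects_expose_data(median_orn):
    doses = np.linspace(-1, 4, 6)
    hm = HillModel(doses, hill_value(median_orn.F_M, median_orn.C_half,
                                     median_orn.n, doses))
    res = hm.fit()
    assert res.model is hm
    assert res.resid == pytest.approx(np.zeros(6), abs=1e-5)
    lm = LatencyModel(doses, latency_value(150.0, 28.0, 60.0, doses))
    lres = lm.fit()
    assert "lam" in lres.summary()
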