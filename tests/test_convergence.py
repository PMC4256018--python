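import numpy as np
import pytest

from ornpn.datatypes import PopulationModel, forward_transform
from ornpn.convergence import (
    DetectionSetting,
    detection_threshold_rate,
    fraction_faster_than,
    rise_time_ms,
    simulate_population_response,
    simulate_population_spontaneous,
    threshold_dose,
    typical_neuron,
)
from ornpn.doseresponse import latency_value


def fixed_model(F=100.0, L=50.0, N=100, spont=(-30.0, 0.0)):
    """Zero-variance population: every neuron fires at F with latency L."""
    med = np.array([F, 0.0, 1.0, L, 1e-9, L])
    M = forward_transform(med)
    M[4] = -30.0  # lam -> ~0 on log scale
    return PopulationModel(M=M, Sigma=np.zeros((6, 6)), N=N,
                           spont_lognorm=spont)


class TestPopulationResponse:
    def test_zero_variance_model_bins_hold_exact_counts(self):
        # N=100 neurons at 100 AP/s: one spike each per 10-ms bin
        psth = simulate_population_response(fixed_model(), dose=10.0,
                                            duration_ms=1000.0, seed=0)
        post = psth.counts[30:95]  # well after every onset (180 + 50 ms)
        assert np.all(post == 100)

    def test_count_conservation(self, orn_model):
        model = orn_model.with_N(300)
        psth = simulate_population_response(model, dose=1.0, seed=1)
        assert psth.total_spikes == psth.counts.sum()
        assert psth.rate_ap_s()[0] == psth.counts[0] * 100.0

    def test_very_low_dose_is_baseline(self):
        model = fixed_model(spont=(np.log(4.0), 0.0))
        quiet = simulate_population_response(model, dose=-30.0, seed=2,
                                             duration_ms=1000.0)
        spont = simulate_population_spontaneous(model, 1000.0, seed=2)
        assert quiet.counts.sum() == spont.counts.sum()

    def test_peak_scales_linearly_in_N(self, orn_model):
        peaks = {}
        for N in (250, 500):
            m = orn_model.with_N(N)
            reps = [simulate_population_response(m, 1.0, 700.0, seed=s).peak_count()
                    for s in range(3)]
            peaks[N] = np.mean(reps)
        assert peaks[500] / peaks[250] == pytest.approx(2.0, rel=0.1)

    def test_recruitment_rise_emerges(self, orn_model):
        model = orn_model.with_N(1500)
        model = PopulationModel(M=model.M, Sigma=model.Sigma, N=1500,
                                spont_lognorm=model.spont_lognorm,
                                spont_total_ap_s=1500 * 27000.0 / 7000.0)
        psth = simulate_population_response(model, dose=1.0,
                                            duration_ms=1000.0, seed=3)
        spont = simulate_population_spontaneous(model, 1000.0, seed=4)
        rise = rise_time_ms(psth, baseline_count=spont.counts.mean())
        assert 50.0 < rise < 450.0  # gradual recruitment, not instantaneous


class TestPopulationSpontaneous:
    def test_fixed_rate_population_exact_bins(self):
        model = fixed_model(N=700, spont=(np.log(4.0), 0.0))
        psth = simulate_population_spontaneous(model, 1000.0, seed=5)
        # 700 regular 4-AP/s trains: 2800 spikes in 1 s, 28 per 10-ms bin
        assert psth.counts.sum() == 2800
        assert psth.counts.mean() == pytest.approx(28.0, abs=0.01)

    def test_zero_rate_population_empty(self):
        psth = simulate_population_spontaneous(fixed_model(N=50), 500.0, seed=6)
        assert psth.total_spikes == 0

    def test_lognormal_population_mean_matches_identity(self):
        model = fixed_model(N=7000, spont=(1.23, 0.71))
        psth = simulate_population_spontaneous(model, 1000.0, seed=7)
        expected = 7000 * np.exp(1.23 + 0.71**2 / 2) / 100.0
        assert psth.counts.mean() == pytest.approx(expected, rel=0.05)

    def test_fixed_total_convention_gives_baseline_270(self, orn_model):
        model = PopulationModel(M=orn_model.M, Sigma=orn_model.Sigma, N=7000,
                                spont_lognorm=orn_model.spont_lognorm,
                                spont_total_ap_s=27000.0)
        psth = simulate_population_spontaneous(model, 1000.0, seed=8)
        assert psth.counts.mean() == pytest.approx(270.0, rel=0.05)


class TestDetection:
    def test_threshold_rate_formula(self):
        assert detection_threshold_rate(DetectionSetting(27000.0, 0.0)) == 27000.0
        assert detection_threshold_rate(DetectionSetting(27000.0, 3.0)) == \
            pytest.approx(27492.95, abs=0.01)
        assert detection_threshold_rate(DetectionSetting(27000.0, 31.0)) == \
            pytest.approx(32093.82, abs=0.01)

    def test_zero_threshold_crosses_at_lowest_dose(self):
        model = fixed_model(N=60, spont=(np.log(4.0), 0.0))
        dose, crossed = threshold_dose(model, DetectionSetting(0.0, 0.0),
                                       [-2.0, 0.0, 2.0], seed=0, n_seeds=2,
                                       duration_ms=400.0)
        assert crossed and dose == -2.0

    def test_unreachable_threshold_returns_sentinel(self):
        model = fixed_model(N=10, spont=(-30.0, 0.0))
        dose, crossed = threshold_dose(model,
                                       DetectionSetting(1e12, 100.0),
                                       [-2.0, 0.0], seed=0, n_seeds=2,
                                       duration_ms=400.0)
        assert not crossed and np.isnan(dose)


class TestTypicalNeuron:
    def test_median_of_symmetric_model(self, orn_model):
        med = typical_neuron(orn_model, 0.5)
        assert med == orn_model.median_params()

    def test_quantile_monotonicity(self, orn_model):
        q25 = typical_neuron(orn_model, 0.25).as_array()
        q50 = typical_neuron(orn_model, 0.50).as_array()
        q75 = typical_neuron(orn_model, 0.75).as_array()
        assert np.all(q25 <= q50) and np.all(q50 <= q75)

    def test_degenerate_model_quantiles_coincide(self, degenerate_model):
        assert typical_neuron(degenerate_model, 0.25) == \
            typical_neuron(degenerate_model, 0.75)

    def test_invalid_quantile(self, orn_model):
        with pytest.raises(ValueError):
            typical_neuron(orn_model, 1.5)


class TestFractionFaster:
    def test_infinite_reference_includes_everyone(self, orn_model):
        assert fraction_faster_than(orn_model, 1.0, np.inf) == 1.0

    def test_median_reference_gives_half(self, orn_model):
        # reference at the population median latency (Monte-Carlo estimate)
        draws = fraction_faster_than(orn_model, 1.0, 1e18, "montecarlo")
        assert draws == 1.0
        # locate the median by bisection on the analytic CDF
        lo, hi = 0.0, 500.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if fraction_faster_than(orn_model, 1.0, mid) < 0.5:
                lo = mid
            else:
                hi = mid
        assert fraction_faster_than(orn_model, 1.0, 0.5 * (lo + hi)) == \
            pytest.approx(0.5, abs=1e-3)

    def test_analytic_matches_montecarlo(self, orn_model, pn_model):
        pn = pn_model.median_params()
        l_ref = latency_value(pn.L_0, pn.lam, pn.L_m, pn.C_half)
        ana = fraction_faster_than(orn_model, pn.C_half, l_ref, "analytic")
        n = 100_000
        mc = fraction_faster_than(orn_model, pn.C_half, l_ref, "montecarlo",
                                  seed=9, n_draws=n)
        se = np.sqrt(ana * (1 - ana) / n)
        assert abs(ana - mc) < 3 * se + 1e-4

    def test_degenerate_latency_block(self, degenerate_model, median_orn):
        l_at_1 = latency_value(median_orn.L_0, median_orn.lam, median_orn.L_m,
                               1.0)
        assert fraction_faster_than(degenerate_model, 1.0, l_at_1 + 1.0) == 1.0
        assert fraction_faster_than(degenerate_model, 1.0, l_at_1 - 1.0) == 0.0
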