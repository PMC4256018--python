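import numpy as np
import pytest

from ornpn.datatypes import NoiseDesign, PopulationModel, StimulusEvent
from ornpn.synthetic import (
    generate_evoked_train,
    generate_recording_session,
    generate_spontaneous_train,
    generate_stimulus_series,
    read_session,
    sample_neuron_params,
    write_session,
)
from ornpn.variance import estimate_within_across

from conftest import make_params


class TestSampleNeuronParams:
    def test_degenerate_distribution_returns_medians(self, degenerate_model,
                                                     median_orn):
        draws = sample_neuron_params(degenerate_model, 5, seed=0)
        for p in draws:
            np.testing.assert_allclose(p.as_array(), median_orn.as_array(),
                                       rtol=1e-12)

    def test_same_seed_is_bit_identical(self, orn_model):
        a = sample_neuron_params(orn_model, 50, seed=42)
        b = sample_neuron_params(orn_model, 50, seed=42)
        assert all(x == y for x, y in zip(a, b))

    def test_sample_means_converge_to_M(self, orn_model):
        draws = sample_neuron_params(orn_model, 5000, seed=1)
        X = np.array([p.as_array() for p in draws])
        X[:, 2] = np.log(X[:, 2])  # back to internal scale for n, lam
        X[:, 4] = np.log(X[:, 4])
        se = np.sqrt(np.diag(orn_model.Sigma) / 5000)
        # redraw truncation biases F_M slightly; 3 SE still holds comfortably
        assert np.all(np.abs(X.mean(axis=0) - orn_model.M) < 3 * se + 1e-9)

    def test_redraw_exhaustion_errors(self):
        # mean F_M far below zero: every draw is rejected
        M = np.array([-1000.0, 0.0, 0.0, 100.0, 3.0, 50.0])
        model = PopulationModel(M=M, Sigma=np.zeros((6, 6)))
        with pytest.raises(RuntimeError, match="redraws"):
            sample_neuron_params(model, 1, seed=0)


class TestEvokedTrain:
    def test_regular_train_arithmetic(self):
        # F=100 AP/s, L=50 ms, T_t=180 -> spikes at 230, 240, ..., 490
        p = make_params(F_M=100.0, C_half=0.0, n=1.0, L_0=50.0, lam=0.0,
                        L_m=50.0)
        train = generate_evoked_train(p, StimulusEvent(dose_log_ng=10.0), 500.0)
        assert train.n_spikes == 27
        np.testing.assert_allclose(train.spikes_ms,
                                   230.0 + 10.0 * np.arange(27), atol=1e-6)

    def test_subthreshold_dose_gives_empty_train(self, median_orn):
        train = generate_evoked_train(median_orn,
                                      StimulusEvent(dose_log_ng=-8.0), 1000.0)
        assert train.n_spikes == 0

    def test_half_maximum_rate_at_ed50(self, median_orn):
        stim = StimulusEvent(dose_log_ng=median_orn.C_half)
        train = generate_evoked_train(median_orn, stim, 10_000.0)
        span_s = (10_000.0 - train.spikes_ms[0]) / 1000.0
        observed = (train.n_spikes - 1) / span_s
        assert observed == pytest.approx(median_orn.F_M / 2, rel=0.02)

    def test_negative_duration_rejected(self, median_orn, simple_stim):
        with pytest.raises(ValueError):
            generate_evoked_train(median_orn, simple_stim, -5.0)

    def test_isi_jitter_preserves_mean_rate(self, median_orn):
        stim = StimulusEvent(dose_log_ng=4.0)
        jittered = generate_evoked_train(median_orn, stim, 5000.0, seed=3,
                                         isi_jitter_cv=0.2)
        regular = generate_evoked_train(median_orn, stim, 5000.0)
        assert jittered.n_spikes == pytest.approx(regular.n_spikes, rel=0.1)


class TestSpontaneousTrain:
    def test_regular_comb(self):
        train = generate_spontaneous_train(4.0, 10_000.0, "regular")
        assert train.n_spikes == 40
        assert np.all(np.diff(train.spikes_ms) == pytest.approx(250.0))

    def test_zero_rate_empty(self):
        assert generate_spontaneous_train(0.0, 1000.0).n_spikes == 0

    def test_poisson_count_within_3_sd(self):
        train = generate_spontaneous_train(10.0, 100_000.0, "poisson", seed=7)
        assert abs(train.n_spikes - 1000) < 3 * np.sqrt(1000)

    def test_unknown_process_rejected(self):
        with pytest.raises(ValueError):
            generate_spontaneous_train(1.0, 100.0, "gamma")


class TestStimulusSeries:
    def test_zero_noise_gives_identical_events(self):
        design = NoiseDesign(onset_heterogeneity_sd_ms=0.0,
                             onset_irregularity_sd_ms=0.0,
                             amp_heterogeneity_cv=0.0, amp_irregularity_cv=0.0)
        events = generate_stimulus_series(design, dose=5.0, seed=0)
        assert len(events) == 140
        assert len({(e.dose_log_ng, e.transport_time_ms) for e in events}) == 1

    def test_onset_variance_components_match_anova_expectations(self):
        # large design so the ANOVA estimates are tight around the truth
        design = NoiseDesign(n_series=150, n_reps=14)
        events = generate_stimulus_series(design, dose=5.0, seed=2)
        est = estimate_within_across([e.transport_time_ms for e in events],
                                     [e.cartridge_id for e in events])
        assert np.sqrt(est["within_var"]) == pytest.approx(4.43, rel=0.10)
        assert np.sqrt(est["between_var"]) == pytest.approx(13.3, rel=0.15)

    def test_amplitude_cv_combines_in_quadrature(self):
        design = NoiseDesign(n_series=300, n_reps=14)
        events = generate_stimulus_series(design, dose=5.0, seed=3)
        amp = 10.0 ** (np.array([e.dose_log_ng for e in events]) - 5.0)
        total_cv = amp.std() / amp.mean()
        assert total_cv == pytest.approx(np.hypot(0.195, 0.05), rel=0.10)


class TestRecordingSession:
    def test_shapes_and_columns(self, tmp_path):
        spikes, meta = generate_recording_session(n_orn=2, n_pn=2,
                                                  trials_per_dose=1,
                                                  n_control=2, seed=5)
        # 2 ORNs x (6 doses + 2 controls) + 2 PNs x (5 doses + 2 controls)
        assert len(meta) == 2 * 8 + 2 * 7
        assert set(spikes.cell_class) == {"ORN", "PN"}
        assert spikes.groupby("trial_id").spike_time_ms.apply(
            lambda s: s.is_monotonic_increasing).all()

    def test_byte_identical_under_same_seed(self, tmp_path):
        for tag in ("a", "b"):
            spikes, meta = generate_recording_session(n_orn=3, n_pn=2, seed=9)
            write_session(spikes, meta, tmp_path / f"s{tag}.csv",
                          tmp_path / f"m{tag}.csv")
        assert (tmp_path / "sa.csv").read_bytes() == (tmp_path / "sb.csv").read_bytes()
        assert (tmp_path / "ma.csv").read_bytes() == (tmp_path / "mb.csv").read_bytes()

    def test_roundtrip_preserves_spike_times(self, tmp_path):
        spikes, meta = generate_recording_session(n_orn=2, n_pn=1, seed=4)
        write_session(spikes, meta, tmp_path / "s.csv", tmp_path / "m.csv")
        back, meta_back = read_session(tmp_path / "s.csv", tmp_path / "m.csv")
        np.testing.assert_allclose(back.spike_time_ms.to_numpy(),
                                   spikes.spike_time_ms.to_numpy(), atol=5e-7)
        assert len(meta_back) == len(meta)

    def test_schema_validation_names_missing_columns(self, tmp_path):
        spikes, meta = generate_recording_session(n_orn=1, n_pn=1, seed=0)
        write_session(spikes, meta, tmp_path / "s.csv", tmp_path / "m.csv")
        broken = spikes.drop(columns=["spike_time_ms"])
        broken.to_csv(tmp_path / "broken.csv", index=False)
        with pytest.raises(ValueError, match="spike_time_ms"):
            read_session(tmp_path / "broken.csv", tmp_path / "m.csv")

    def test_empty_dose_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_recording_session(orn_doses=(), seed=0)
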