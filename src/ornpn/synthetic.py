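"""Synthetic spike-train datasets with the statistical structure the
analysis assumes.

The generator emulates single-sensillum / intracellular recordings of
pheromone-sensitive first-order neurons (ORNs) and their postsynaptic
projection neurons (PNs): phasic evoked trains with dose-dependent rate and
first-spike latency, lognormal spontaneous firing, control (solvent) trials,
and a two-level stimulus-noise design in which repeated puffs from one
cartridge vary a little (irregularity) and identically prepared cartridges
vary more (heterogeneity).

Evoked trains are *regular*: first spike at ``T_t + L(C)`` and interspike
interval ``1000 / F(C)`` ms.  An optional Gaussian ISI jitter is available
for robustness experiments but is off by default.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .datatypes import (
    PARAM_FIELDS,
    NeuronParamVector,
    NoiseDesign,
    PopulationModel,
    SpikeTrain,
    StimulusEvent,
    back_transform,
)
from .defaults import (
    CONTROL_F_RAW,
    CONTROL_LATENCY,
    ORN_DOSES,
    PN_DOSES,
    TRIAL_CV_F,
    TRIAL_CV_L,
    default_orn_model,
    default_pn_model,
)
from .doseresponse import hill_value, latency_value

__all__ = [
    "sample_neuron_params",
    "generate_evoked_train",
    "generate_spontaneous_train",
    "generate_stimulus_series",
    "generate_recording_session",
    "write_session",
    "read_session",
    "SPIKE_COLUMNS",
    "META_COLUMNS",
]

SPIKE_COLUMNS = ["neuron_id", "cell_class", "trial_id", "dose_log_ng",
                 "is_control", "spike_time_ms"]
META_COLUMNS = ["neuron_id", "trial_id", "dose_log_ng", "is_control",
                "cartridge_id", "valve_open_ms", "window_start_ms",
                "window_end_ms"]

#: redraw limits for truncated multinormal sampling
_MAX_REDRAW = 100
_L_M_FLOOR = -50.0


def _draw_param_vector(model: PopulationModel, chol: np.ndarray,
                       rng: np.random.Generator) -> NeuronParamVector:
    for _ in range(_MAX_REDRAW):
        vec = model.M + chol @ rng.standard_normal(6)
        vec = back_transform(vec)
        if vec[PARAM_FIELDS.index("F_M")] > 0 and vec[PARAM_FIELDS.index("L_m")] > _L_M_FLOOR:
            return NeuronParamVector.from_array(vec)
    raise RuntimeError(
        f"exceeded {_MAX_REDRAW} redraws sampling a valid parameter vector; "
        "check the population model's mean and covariance"
    )


def _cholesky(model: PopulationModel) -> np.ndarray:
    # Sigma is validated PSD at construction; lift tiny negative eigenvalues
    # arising from floating-point noise before factorisation.
    Sigma = model.Sigma
    try:
        return np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(Sigma)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def sample_neuron_params(model: PopulationModel, count: int,
                         seed: int | np.random.Generator) -> list[NeuronParamVector]:
    """Draw ``count`` six-parameter neurons from the population model.

    Draws come from the multinormal (M, Sigma); the ``n`` and ``lam``
    coordinates are exponentiated after drawing (lognormal marginals).
    Draws with non-positive maximum rate or an absurd latency floor are
    redrawn (at most 100 times each).  The same seed gives identical output.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chol = _cholesky(model)
    return [_draw_param_vector(model, chol, rng) for _ in range(count)]


def generate_evoked_train(
    params: NeuronParamVector,
    stim: StimulusEvent,
    duration_ms: float,
    seed: int | np.random.Generator | None = None,
    isi_jitter_cv: float = 0.0,
    f_floor_ap_s: float = 0.1,
    neuron_id: str = "n0",
    trial_id: str = "t0",
    window_start_ms: float = 0.0,
) -> SpikeTrain:
    """Regular evoked train: first spike at T_t + L(C), then ISIs of 1000/F(C).

    Rates below ``f_floor_ap_s`` produce an empty train.  With
    ``isi_jitter_cv`` > 0 each interval is jittered by a Gaussian factor
    (robustness experiments only; the stated model is strictly regular).
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be > 0")
    if stim.is_control or stim.dose_log_ng is None:
        raise ValueError("generate_evoked_train needs a pheromone stimulus")
    C = stim.dose_log_ng
    F = hill_value(params.F_M, params.C_half, params.n, C)
    L = latency_value(params.L_0, params.lam, params.L_m, C)
    window = (min(window_start_ms, 0.0), duration_ms)
    if F < f_floor_ap_s:
        spikes = np.empty(0)
    else:
        isi = 1000.0 / F
        t0 = stim.valve_open_ms + stim.transport_time_ms + L
        if t0 >= duration_ms:
            spikes = np.empty(0)
        elif isi_jitter_cv > 0:
            rng = (seed if isinstance(seed, np.random.Generator)
                   else np.random.default_rng(seed))
            gaps = isi * np.maximum(
                1.0 + isi_jitter_cv * rng.standard_normal(
                    int(math.ceil((duration_ms - t0) / isi)) + 8), 0.05)
            spikes = t0 + np.concatenate(([0.0], np.cumsum(gaps)))
            spikes = spikes[spikes < duration_ms]
        else:
            count = int(math.floor((duration_ms - t0) / isi - 1e-12)) + 1
            spikes = t0 + isi * np.arange(count)
    spikes = spikes[spikes >= window[0]]
    return SpikeTrain(neuron_id=neuron_id, trial_id=trial_id, stimulus=stim,
                      spikes_ms=spikes, window_ms=window)


def generate_spontaneous_train(
    rate_ap_s: float,
    duration_ms: float,
    process: str = "regular",
    seed: int | np.random.Generator | None = None,
    start_ms: float = 0.0,
    neuron_id: str = "n0",
    trial_id: str = "t0",
) -> SpikeTrain:
    """Background train at a constant mean rate.

    ``regular`` places spikes at the centres of consecutive ISI slots (a
    deterministic comb); ``poisson`` draws i.i.d. exponential intervals.
    """
    if rate_ap_s < 0:
        raise ValueError("rate must be >= 0")
    if duration_ms <= start_ms:
        raise ValueError("duration_ms must exceed start_ms")
    span = duration_ms - start_ms
    if rate_ap_s == 0:
        spikes = np.empty(0)
    elif process == "regular":
        isi = 1000.0 / rate_ap_s
        count = int(math.floor(span / isi))
        spikes = start_ms + isi * (np.arange(count) + 0.5)
    elif process == "poisson":
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        mean_isi = 1000.0 / rate_ap_s
        n_guess = max(16, int(span / mean_isi * 1.5) + 8)
        gaps = rng.exponential(mean_isi, size=n_guess)
        t = start_ms + np.cumsum(gaps)
        while t.size and t[-1] < duration_ms:
            gaps = rng.exponential(mean_isi, size=n_guess)
            t = np.concatenate([t, t[-1] + np.cumsum(gaps)])
        spikes = t[t < duration_ms]
    else:
        raise ValueError(f"unknown process {process!r}")
    return SpikeTrain(neuron_id=neuron_id, trial_id=trial_id, stimulus=None,
                      spikes_ms=spikes,
                      window_ms=(min(start_ms, 0.0), duration_ms))


def generate_stimulus_series(
    design: NoiseDesign,
    dose: float,
    seed: int | np.random.Generator | None = None,
    base: StimulusEvent | None = None,
) -> list[StimulusEvent]:
    """Stimulus events for an n_series x n_reps two-level noise design.

    Each series shares one cartridge: a per-series onset offset
    ~ N(0, heterogeneity SD) and amplitude factor (mean 1, heterogeneity CV)
    apply to all its repetitions; each repetition adds a per-trial onset
    offset ~ N(0, irregularity SD) and amplitude factor (mean 1, irregularity
    CV).  Amplitude factors act multiplicatively on the load, i.e. additively
    (log10) on the dose.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if base is None:
        base = StimulusEvent(dose_log_ng=dose)
    events: list[StimulusEvent] = []
    for s in range(design.n_series):
        d_onset = rng.normal(0.0, design.onset_heterogeneity_sd_ms) \
            if design.onset_heterogeneity_sd_ms > 0 else 0.0
        d_amp = rng.normal(1.0, design.amp_heterogeneity_cv) \
            if design.amp_heterogeneity_cv > 0 else 1.0
        for r in range(design.n_reps):
            e_onset = rng.normal(0.0, design.onset_irregularity_sd_ms) \
                if design.onset_irregularity_sd_ms > 0 else 0.0
            e_amp = rng.normal(1.0, design.amp_irregularity_cv) \
                if design.amp_irregularity_cv > 0 else 1.0
            amp = max(d_amp * e_amp, 1e-3)
            events.append(replace(
                base,
                dose_log_ng=dose + math.log10(amp),
                transport_time_ms=base.transport_time_ms + d_onset + e_onset,
                cartridge_id=f"cart{s:02d}",
            ))
    return events


# ---------------------------------------------------------------------------
# whole recording sessions
# ---------------------------------------------------------------------------


def _regular_burst(rate_ap_s, t0, t_end):
    """Regular spikes at a fixed rate from t0 (inclusive) to t_end."""
    if rate_ap_s < 0.1 or t0 >= t_end:
        return None
    isi = 1000.0 / rate_ap_s
    count = int(math.floor((t_end - t0) / isi - 1e-12)) + 1
    return t0 + isi * np.arange(count)


def _control_transient(rng, ctrl_mean, duration_ms, latency_law=(250.0, 60.0),
                       transport_ms=180.0, span_ms=400.0):
    """Response to the puff itself (solvent / clean air): a brief regular
    burst at the neuron's control rate."""
    f_ctrl = max(rng.normal(ctrl_mean, 0.2 * ctrl_mean), 0.0)
    lat = max(rng.normal(*latency_law), 10.0)
    t0 = transport_ms + lat
    return _regular_burst(f_ctrl, t0, min(t0 + span_ms, duration_ms))


def _session_trial(params, stim, rng, duration_ms, window_start_ms, spont_rate,
                   trial_cv_f, trial_cv_l, ctrl_mean, ctrl_latency,
                   neuron_id, trial_id):
    """One trial: evoked train (with within-neuron rate/latency jitter)
    superposed on the puff's control transient and Poisson background.

    The control transient rides on pheromone trials too - that is what makes
    the downstream F = F_raw - F_c correction meaningful."""
    C = stim.dose_log_ng
    F = hill_value(params.F_M, params.C_half, params.n, C)
    L = latency_value(params.L_0, params.lam, params.L_m, C)
    if trial_cv_f > 0:
        F *= max(1.0 + trial_cv_f * rng.standard_normal(), 0.0)
    if trial_cv_l > 0:
        L *= max(1.0 + trial_cv_l * rng.standard_normal(), 0.05)
    spikes = []
    if F >= 0.1:
        t0 = stim.valve_open_ms + stim.transport_time_ms + L
        evoked = _regular_burst(F, t0, duration_ms)
        if evoked is not None:
            spikes.append(evoked)
    ctrl = _control_transient(rng, ctrl_mean, duration_ms,
                              latency_law=ctrl_latency,
                              transport_ms=stim.transport_time_ms)
    if ctrl is not None:
        spikes.append(ctrl)
    if spont_rate > 0:
        bg = generate_spontaneous_train(
            spont_rate, duration_ms, process="poisson", seed=rng,
            start_ms=window_start_ms).spikes_ms
        spikes.append(bg)
    if spikes:
        merged = np.unique(np.concatenate(spikes))
    else:
        merged = np.empty(0)
    merged = merged[(merged >= window_start_ms) & (merged < duration_ms)]
    return SpikeTrain(neuron_id=neuron_id, trial_id=trial_id, stimulus=stim,
                      spikes_ms=merged, window_ms=(window_start_ms, duration_ms))


def generate_recording_session(
    orn_model: PopulationModel | None = None,
    pn_model: PopulationModel | None = None,
    n_orn: int = 38,
    n_pn: int = 47,
    orn_doses=ORN_DOSES,
    pn_doses=PN_DOSES,
    trials_per_dose: int | dict = None,
    n_control: int = 4,
    noise: NoiseDesign | None = None,
    seed: int = 0,
    duration_ms: float = 1500.0,
    window_start_ms: float = -5000.0,
    trial_cv_f: float = TRIAL_CV_F,
    trial_cv_l: float = TRIAL_CV_L,
    return_truth: bool = False,
) -> tuple[pd.DataFrame, ...]:
    """Generate a full two-population recording session.

    Returns ``(spikes, metadata)`` data frames in the package's columnar
    interchange format (one row per spike / one row per trial); with
    ``return_truth`` a third frame carries each neuron's generating
    parameters.  Every draw is governed by ``seed``; identical seeds give
    identical tables.

    ``noise`` adds two-level stimulus noise (a fresh cartridge per dose
    series, trial-level jitter on onset and amplitude); ``trial_cv_f`` /
    ``trial_cv_l`` set the within-neuron irregularity of rate and latency.
    Set all of these to zero/None for a noiseless session whose fits recover
    the generating parameters exactly.
    """
    if not len(orn_doses) or not len(pn_doses):
        raise ValueError("dose grids must be non-empty")
    orn_model = orn_model if orn_model is not None else default_orn_model()
    pn_model = pn_model if pn_model is not None else default_pn_model()
    # recording protocol: each ORN once per dose, each PN twice per dose
    if trials_per_dose is None:
        trials_per_dose = {"ORN": 1, "PN": 2}
    if isinstance(trials_per_dose, int):
        trials_per_dose = {"ORN": trials_per_dose, "PN": trials_per_dose}
    rng = np.random.default_rng(seed)
    spikes_rows: list[tuple] = []
    meta_rows: list[tuple] = []
    truth_rows: list[dict] = []
    seen_ids: set[str] = set()

    for cls, model, n_neu, doses in (
        ("ORN", orn_model, n_orn, orn_doses),
        ("PN", pn_model, n_pn, pn_doses),
    ):
        params_list = sample_neuron_params(model, n_neu, rng)
        ctrl_mu, ctrl_sd = CONTROL_F_RAW[cls]
        ctrl_latency = CONTROL_LATENCY[cls]
        mu_sp, sd_sp = model.spont_lognorm
        for i, params in enumerate(params_list):
            neuron_id = f"{cls}{i:03d}"
            if neuron_id in seen_ids:
                raise ValueError(f"conflicting neuron id {neuron_id}")
            seen_ids.add(neuron_id)
            spont_rate = float(np.exp(rng.normal(mu_sp, sd_sp)))
            # each neuron's control responses scatter about one neuron-level mean
            ctrl_mean = max(rng.normal(ctrl_mu, ctrl_sd), 0.5)
            truth_rows.append({"neuron_id": neuron_id, "cell_class": cls,
                               **{f: getattr(params, f) for f in PARAM_FIELDS},
                               "spont_rate": spont_rate,
                               "ctrl_mean": ctrl_mean})
            trial_no = 0
            for dose in doses:
                for _ in range(trials_per_dose[cls]):
                    if noise is not None:
                        d_onset = rng.normal(0.0, noise.onset_heterogeneity_sd_ms)
                        e_onset = rng.normal(0.0, noise.onset_irregularity_sd_ms)
                        amp = max(rng.normal(1.0, noise.amp_heterogeneity_cv)
                                  * rng.normal(1.0, noise.amp_irregularity_cv), 1e-3)
                        stim = StimulusEvent(
                            dose_log_ng=dose + math.log10(amp),
                            transport_time_ms=180.0 + d_onset + e_onset,
                            cartridge_id=f"{cls}{i:03d}-d{dose:+.1f}",
                        )
                    else:
                        stim = StimulusEvent(dose_log_ng=dose,
                                             cartridge_id=f"d{dose:+.1f}")
                    trial_id = f"{neuron_id}-t{trial_no:03d}"
                    trial_no += 1
                    train = _session_trial(
                        params, stim, rng, duration_ms, window_start_ms,
                        spont_rate, trial_cv_f, trial_cv_l, ctrl_mean,
                        ctrl_latency, neuron_id, trial_id)
                    meta_rows.append((neuron_id, trial_id, dose, False,
                                      stim.cartridge_id, 0.0,
                                      window_start_ms, duration_ms))
                    for t in train.spikes_ms:
                        spikes_rows.append((neuron_id, cls, trial_id, dose,
                                            False, float(t)))
            # control trials: the puff transient alone plus background
            for k in range(n_control):
                trial_id = f"{neuron_id}-c{k:03d}"
                spikes = []
                ctrl = _control_transient(rng, ctrl_mean, duration_ms,
                                          latency_law=ctrl_latency)
                if ctrl is not None:
                    spikes.append(ctrl)
                if spont_rate > 0:
                    spikes.append(generate_spontaneous_train(
                        spont_rate, duration_ms, "poisson", seed=rng,
                        start_ms=window_start_ms).spikes_ms)
                merged = (np.unique(np.concatenate(spikes))
                          if spikes else np.empty(0))
                merged = merged[(merged >= window_start_ms) & (merged < duration_ms)]
                meta_rows.append((neuron_id, trial_id, np.nan, True, "control",
                                  0.0, window_start_ms, duration_ms))
                for t in merged:
                    spikes_rows.append((neuron_id, cls, trial_id, np.nan,
                                        True, float(t)))

    spikes_df = pd.DataFrame(spikes_rows, columns=SPIKE_COLUMNS)
    meta_df = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    if return_truth:
        return spikes_df, meta_df, pd.DataFrame(truth_rows)
    return spikes_df, meta_df


# ---------------------------------------------------------------------------
# interchange files
# ---------------------------------------------------------------------------


def write_session(spikes: pd.DataFrame, meta: pd.DataFrame,
                  spikes_path, meta_path) -> None:
    """Write the spike and metadata tables as CSV (UTF-8, '.' decimal,
    missing values as empty fields)."""
    spikes.to_csv(spikes_path, index=False, float_format="%.6f")
    meta.to_csv(meta_path, index=False, float_format="%.6f")


def read_session(spikes_path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    spikes = pd.read_csv(spikes_path)
    meta = pd.read_csv(meta_path)
    for df, cols, name in ((spikes, SPIKE_COLUMNS, "spike table"),
                           (meta, META_COLUMNS, "metadata table")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} is missing columns {missing}")
    return spikes, meta
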