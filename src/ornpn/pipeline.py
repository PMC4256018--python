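"""End-to-end orchestration over the CSV/JSON interchange formats.

Each stage reads and writes only the columnar interfaces, so any stage can
be re-run from files produced earlier (or by other tools emitting the same
schema).  All stages are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import convergence, metrics, popstats, transfer, variance
from .datatypes import NoiseDesign, PopulationModel, SpikeTrain, StimulusEvent
from .defaults import default_noise_design, default_orn_model, default_pn_model
from .doseresponse import fit_hill, fit_latency_line
from .synthetic import generate_recording_session, generate_stimulus_series, read_session, write_session

log = logging.getLogger("ornpn")

RESPONSE_COLUMNS = ["neuron_id", "cell_class", "trial_id", "dose_log_ng",
                    "F_raw", "F_c", "F", "T_ms", "L_ms", "significant"]
FIT_COLUMNS = ["neuron_id", "cell_class", "F_M", "C_half", "n", "C_0", "C_s",
               "Delta_C", "L_0", "lam", "L_m", "L_M", "Delta_L",
               "rss_F", "rss_L", "converged", "well_estimated", "latency_converged"]


def stage_simulate(out_dir: Path, seed: int,
                   orn_model: PopulationModel | None = None,
                   pn_model: PopulationModel | None = None,
                   noise: NoiseDesign | None = None,
                   n_orn: int = 38, n_pn: int = 47,
                   trials_per_dose: int | dict | None = None) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    orn_model = orn_model or default_orn_model()
    pn_model = pn_model or default_pn_model()
    noise = noise if noise is not None else default_noise_design()
    spikes, meta = generate_recording_session(
        orn_model, pn_model, n_orn=n_orn, n_pn=n_pn,
        trials_per_dose=trials_per_dose, noise=noise, seed=seed)
    write_session(spikes, meta, out_dir / "spikes.csv", out_dir / "metadata.csv")
    orn_model.to_json(out_dir / "orn_model.json")
    pn_model.to_json(out_dir / "pn_model.json")
    log.info("simulate: %d spike rows, %d trials (seed %d)",
             len(spikes), len(meta), seed)
    return {"spikes": len(spikes), "trials": len(meta)}


def _train_from_rows(meta_row, spike_times) -> SpikeTrain:
    if meta_row.is_control:
        stim = StimulusEvent(dose_log_ng=None, is_control=True,
                             cartridge_id=meta_row.cartridge_id)
    else:
        stim = StimulusEvent(dose_log_ng=float(meta_row.dose_log_ng),
                             cartridge_id=meta_row.cartridge_id)
    return SpikeTrain(
        neuron_id=meta_row.neuron_id, trial_id=meta_row.trial_id, stimulus=stim,
        spikes_ms=np.sort(np.asarray(spike_times, dtype=float)),
        window_ms=(float(meta_row.window_start_ms), float(meta_row.window_end_ms)))


def stage_metrics(out_dir: Path) -> pd.DataFrame:
    """Per-trial response measures from the spike/metadata tables."""
    out_dir = Path(out_dir)
    spikes, meta = read_session(out_dir / "spikes.csv", out_dir / "metadata.csv")
    by_trial = {k: g["spike_time_ms"].to_numpy() for k, g in spikes.groupby("trial_id")}
    classes = spikes.drop_duplicates("neuron_id").set_index("neuron_id")["cell_class"]
    rows = []
    # first pass: control F_raw per neuron
    control_raw: dict[str, list[float]] = {}
    trains: dict[str, SpikeTrain] = {}
    for row in meta.itertuples(index=False):
        train = _train_from_rows(row, by_trial.get(row.trial_id, ()))
        trains[row.trial_id] = train
        if row.is_control:
            rate = metrics.estimate_rate(train)
            f_raw, _ = metrics.peak_rate(rate)
            control_raw.setdefault(row.neuron_id, []).append(f_raw)
    f_c = {nid: metrics.control_mean(v) for nid, v in control_raw.items()}
    for row in meta.itertuples(index=False):
        train = trains[row.trial_id]
        meas = metrics.measure_response(train, F_c=f_c.get(row.neuron_id, 0.0))
        rows.append((row.neuron_id, classes.get(row.neuron_id, ""),
                     row.trial_id, meas.dose_log_ng, meas.F_raw, meas.F_c,
                     meas.F, meas.T_ms, meas.L_ms, meas.significant))
    resp = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    resp.to_csv(out_dir / "responses.csv", index=False, float_format="%.6f")
    log.info("metrics: %d trials measured", len(resp))
    return resp


def fit_neuron(doses, F, L, significant, F_0: float = 5.0,
               rate_points: str = "zero",
               min_recognizable: float = 10.0,
               latency_min_rate: float = 25.0) -> dict:
    """Fit one neuron's Hill curve and latency line from per-trial points.

    ``rate_points`` selects which control-corrected rates enter the Hill
    fit: "zero" (default) anchors trials below the response criterion
    (F < F_0: kernel bumps of sparse extra spikes on the control plateau
    are not a response) at exactly F = 0 and drops the ambiguous band up to
    2 F_0; "all" uses every corrected rate as measured; "significant" drops
    non-significant trials.  Latencies come from significant trials whose
    corrected rate clears ``latency_min_rate`` - below ~25 AP/s a first
    spike cannot be told apart from the control transient and spontaneous
    bursts.
    """
    doses = np.asarray(doses, float)
    F = np.asarray(F, float)
    L = np.asarray(L, float)
    significant = np.asarray(significant, bool)
    out = {c: float("nan") for c in FIT_COLUMNS if c not in
           ("neuron_id", "cell_class", "converged", "well_estimated")}
    out["converged"] = False
    out["well_estimated"] = False
    out["latency_converged"] = False
    if rate_points == "all":
        f_fit = np.clip(F, 0.0, None)
        rate_mask = np.isfinite(doses) & np.isfinite(f_fit)
    elif rate_points == "zero":
        # below the single-spike kernel bump (~8 AP/s) there is clearly no
        # response (anchor at 0); between that and the minimum recognizable
        # response the measurement is ambiguous and the trial is dropped
        f_fit = np.clip(F, 0.0, None)
        no_resp = F < 0.5 * min_recognizable
        f_fit[no_resp] = 0.0
        ambiguous = (F >= 0.5 * min_recognizable) & (F < min_recognizable)
        rate_mask = np.isfinite(doses) & np.isfinite(f_fit) & ~ambiguous
    elif rate_points == "significant":
        f_fit = np.clip(F, 0.0, None)
        rate_mask = significant & np.isfinite(doses) & np.isfinite(F)
    else:
        raise ValueError(f"unknown rate_points mode {rate_points!r}")
    converged_F = converged_L = False
    if rate_mask.sum() >= 4 and np.ptp(doses[rate_mask]) > 0:
        hill = fit_hill(doses[rate_mask], f_fit[rate_mask], F_0=F_0)
        out.update(F_M=hill.F_M, C_half=hill.C_half, n=hill.n, rss_F=hill.rss)
        c0, cs, dc = hill.characteristics()
        out.update(C_0=c0, C_s=cs, Delta_C=dc)
        converged_F = hill.converged
    # the asymptote is well estimated only if the curve effectively
    # saturates inside the tested dose range (otherwise F_M is an
    # extrapolation beyond the data)
    if converged_F and np.isfinite(out["F_M"]):
        from .doseresponse import hill_value

        f_top = hill_value(out["F_M"], out["C_half"], out["n"],
                           np.max(doses[rate_mask]))
        out["well_estimated"] = bool(f_top >= 0.85 * out["F_M"])
    lat_mask = significant & np.isfinite(L) & (F >= latency_min_rate)
    if (lat_mask.sum() >= 3 and np.unique(doses[lat_mask]).size >= 3
            and np.ptp(doses[lat_mask]) >= 2.0):
        lat = fit_latency_line(doses[lat_mask], L[lat_mask])
        out.update(L_0=lat.L_0, lam=lat.lam, L_m=lat.L_m, rss_L=lat.rss)
        L_M, dL = lat.characteristics(out["C_0"])
        out.update(L_M=L_M, Delta_L=dL)
        converged_L = lat.converged
        out["latency_converged"] = bool(lat.converged)
    out["converged"] = bool(converged_F and converged_L)
    return out


def stage_fit(out_dir: Path, F_0: float = 5.0) -> pd.DataFrame:
    out_dir = Path(out_dir)
    resp = pd.read_csv(out_dir / "responses.csv")
    missing = [c for c in RESPONSE_COLUMNS if c not in resp.columns]
    if missing:
        raise ValueError(f"responses.csv is missing columns {missing}")
    rows = []
    evoked = resp[resp["dose_log_ng"].notna()]
    for (nid, cls), g in evoked.groupby(["neuron_id", "cell_class"], sort=True):
        fit = fit_neuron(g["dose_log_ng"], g["F"], g["L_ms"], g["significant"],
                         F_0=F_0)
        rows.append({"neuron_id": nid, "cell_class": cls, **fit})
    fits = pd.DataFrame(rows, columns=FIT_COLUMNS)
    fits.to_csv(out_dir / "fits.csv", index=False, float_format="%.6f")
    log.info("fit: %d neurons, %d converged", len(fits),
             int(fits["converged"].sum()))
    return fits


def median_properties(fits: pd.DataFrame) -> dict:
    """Median fitted properties of one cell class: rate properties over
    well-estimated fits, latency properties over successful latency fits."""
    rate_ok = fits[fits["well_estimated"].astype(bool)]
    lat_ok = fits[fits["latency_converged"].astype(bool)]
    out = {k: float(v) for k, v in
           rate_ok[["F_M", "C_half", "n", "C_0", "C_s", "Delta_C"]]
           .median().items()}
    out.update({k: float(v) for k, v in
                lat_ok[["L_0", "lam", "L_m", "L_M", "Delta_L"]]
                .median().items()})
    out["n_rate_fits"] = int(len(rate_ok))
    out["n_latency_fits"] = int(len(lat_ok))
    return out


def stage_popstats(out_dir: Path) -> dict:
    """Distribution fits, correlations and estimated population models."""
    out_dir = Path(out_dir)
    fits = pd.read_csv(out_dir / "fits.csv")
    dist_rows, corr_frames, models = [], [], {}
    for cls, g in fits.groupby("cell_class"):
        ok = g[g["converged"].astype(bool)]
        for prop, family in (("F_M", "normal"), ("Delta_C", "lognormal"),
                             ("L_M", "lognormal"), ("L_m", "normal")):
            vals = ok[prop].dropna()
            vals = vals[vals > 0] if family == "lognormal" else vals
            if len(vals) >= 5:
                d = popstats.fit_distribution(vals, family)
                dist_rows.append((cls, prop, d.family, d.mu, d.sigma,
                                  d.ks_stat, d.ks_p, d.n_obs))
        props = ok[["F_M", "C_half", "n", "C_0", "C_s", "Delta_C",
                    "L_0", "lam", "L_m", "L_M", "Delta_L"]].dropna()
        if len(props) >= 5:
            corr = popstats.correlation_matrix(props)
            corr.insert(0, "cell_class", cls)
            corr_frames.append(corr)
        complete = ok[["F_M", "C_half", "n", "L_0", "lam", "L_m"]].dropna()
        if len(complete) >= 7:
            M, Sigma = popstats.estimate_multinormal(complete)
            models[cls] = PopulationModel(M=M, Sigma=Sigma, label=cls)
            models[cls].to_json(out_dir / f"{cls.lower()}_model_refit.json")
    pd.DataFrame(dist_rows, columns=["cell_class", "property", "family", "mu",
                                     "sigma", "ks_stat", "ks_p", "n_obs"]
                 ).to_csv(out_dir / "distributions.csv", index=False)
    if corr_frames:
        pd.concat(corr_frames).to_csv(out_dir / "correlations.csv", index=False)
    log.info("popstats: %d distribution fits, %d refit models",
             len(dist_rows), len(models))
    return {"distributions": len(dist_rows), "models": sorted(models)}


def stage_variance(out_dir: Path, seed: int,
                   noise: NoiseDesign | None = None) -> pd.DataFrame:
    """Stimulus-noise estimation on a fresh series x repetitions design."""
    out_dir = Path(out_dir)
    noise = noise if noise is not None else default_noise_design()
    events = generate_stimulus_series(noise, dose=5.0, seed=seed)
    series = [e.cartridge_id for e in events]
    onset = variance.estimate_within_across(
        [e.transport_time_ms for e in events], series)
    amp = variance.estimate_within_across(
        [10.0 ** (e.dose_log_ng - 5.0) for e in events], series)
    rows = pd.DataFrame([
        {"variable": "onset_ms", "within_sd": np.sqrt(onset["within_var"]),
         "between_sd": np.sqrt(onset["between_var"]),
         "within_cv": onset["within_cv"], "between_cv": onset["between_cv"]},
        {"variable": "amplitude", "within_sd": np.sqrt(amp["within_var"]),
         "between_sd": np.sqrt(amp["between_var"]),
         "within_cv": amp["within_cv"], "between_cv": amp["between_cv"]},
    ])
    rows.to_csv(out_dir / "variance_components.csv", index=False)
    log.info("variance: onset within/between SD %.2f / %.2f ms",
             rows.loc[0, "within_sd"], rows.loc[0, "between_sd"])
    return rows


def stage_transfer(out_dir: Path) -> dict:
    """Median transfer functions from the fitted parameter medians."""
    out_dir = Path(out_dir)
    fits = pd.read_csv(out_dir / "fits.csv")
    med = {}
    for cls, g in fits.groupby("cell_class"):
        rate_ok = g[g["well_estimated"].astype(bool)]
        lat_ok = g[g["latency_converged"].astype(bool)]
        med[cls] = pd.concat([rate_ok[["F_M", "C_half", "n"]].median(),
                              lat_ok[["L_0", "lam", "L_m"]].median()])
    if not {"ORN", "PN"} <= set(med):
        raise ValueError("transfer stage needs converged ORN and PN fits")
    orn_rate = tuple(med["ORN"][["F_M", "C_half", "n"]])
    pn_rate = tuple(med["PN"][["F_M", "C_half", "n"]])
    orn_lat = tuple(med["ORN"][["L_0", "lam"]])
    pn_lat = tuple(med["PN"][["L_0", "lam", "L_m"]])
    rate_curve = transfer.TransferCurve.from_params(orn_rate, pn_rate, "rate")
    lat_curve = transfer.TransferCurve.from_params(
        tuple(med["ORN"][["L_0", "lam", "L_m"]]), pn_lat, "latency")
    pd.DataFrame({"orn_rate_ap_s": rate_curve.inputs,
                  "pn_rate_ap_s": rate_curve.outputs}
                 ).to_csv(out_dir / "transfer_rate.csv", index=False)
    pd.DataFrame({"orn_latency_ms": lat_curve.inputs,
                  "pn_latency_ms": lat_curve.outputs}
                 ).to_csv(out_dir / "transfer_latency.csv", index=False)
    params = {
        "K": rate_curve.K,
        "F_half_input_ap_s": rate_curve.F_half_input,
        "latency_slope": lat_curve.slope,
        "latency_intercept_ms": lat_curve.intercept,
        "sensitivity_fold_change": transfer.sensitivity_shift(
            orn_rate[1], pn_rate[1]),
    }
    with open(out_dir / "transfer_params.json", "w", encoding="utf-8") as fh:
        json.dump(params, fh, indent=2)
    log.info("transfer: slope %.3f, %d-fold sensitivity shift",
             params["latency_slope"], round(params["sensitivity_fold_change"]))
    return params


def stage_population(out_dir: Path, seed: int, dose: float = 1.0,
                     model: PopulationModel | None = None,
                     duration_ms: float = 800.0) -> dict:
    """Population convergence simulation and detection summary."""
    out_dir = Path(out_dir)
    if model is None:
        model_path = out_dir / "orn_model.json"
        model = (PopulationModel.from_json(model_path) if model_path.exists()
                 else default_orn_model())
    model = PopulationModel.from_dict(
        {**model.to_dict(), "spont_total_ap_s": 27000.0})
    psth = convergence.simulate_population_response(
        model, dose, duration_ms=duration_ms, seed=seed)
    pd.DataFrame({"bin_start_ms": psth.bin_edges_ms[:-1],
                  "count": psth.counts}
                 ).to_csv(out_dir / "psth.csv", index=False)
    spont = convergence.simulate_population_spontaneous(
        model, duration_ms=duration_ms, seed=seed + 1)
    setting = convergence.DetectionSetting(
        baseline_total_ap_s=model.spont_total_ap_s, r=3.0)
    pn_med = (default_pn_model().median_params())
    from .doseresponse import latency_value

    l_ref = latency_value(pn_med.L_0, pn_med.lam, pn_med.L_m,
                          pn_med.C_half)
    summary = {
        "dose": dose,
        "peak_count_per_bin": psth.peak_count(),
        "spont_mean_count_per_bin": float(spont.counts.mean()),
        "detection_threshold_ap_s": convergence.detection_threshold_rate(setting),
        "fraction_faster_than_typical_pn": convergence.fraction_faster_than(
            model, pn_med.C_half, l_ref, mode="analytic"),
    }
    with open(out_dir / "population_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    log.info("population: peak %d spikes/bin at dose %.1f",
             summary["peak_count_per_bin"], dose)
    return summary


def run_all(out_dir: Path, seed: int = 0, **kwargs) -> dict:
    """Chain every stage on synthetic data and write a summary report."""
    out_dir = Path(out_dir)
    report = {"seed": seed}
    report["simulate"] = stage_simulate(out_dir, seed, **kwargs)
    stage_metrics(out_dir)
    fits = stage_fit(out_dir)
    report["median_fits"] = {
        cls: median_properties(g)
        for cls, g in fits.groupby("cell_class")
    }
    report["popstats"] = stage_popstats(out_dir)
    report["variance"] = stage_variance(out_dir, seed + 1).to_dict("records")
    report["transfer"] = stage_transfer(out_dir)
    report["population"] = stage_population(out_dir, seed + 2)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
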