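"""Reconstructed default population models for ORNs and PNs.

The original recordings are not distributed, so these models are a
*reconstruction*: the medians come from the published summary statistics of
the fitted dose-response curves (maximum firing rates 163 / 62 AP/s, Hill
coefficients 0.81 / 0.79, maximum latencies 164 / 107 ms, latency ranges
104 / 64 ms, a 2.7 log-unit ED50 separation and a 0.65 latency-transfer
slope), and the spreads and correlations are chosen so that the per-dose
population distributions show the reported coefficient-of-variation
structure.  See docs/methods.md for the full derivation and its limits.
"""

from __future__ import annotations

import numpy as np

from .datatypes import PARAM_FIELDS, NoiseDesign, PopulationModel, forward_transform

__all__ = [
    "default_orn_model",
    "default_pn_model",
    "default_noise_design",
    "ORN_DOSES",
    "PN_DOSES",
    "CONTROL_F_RAW",
    "TRIAL_CV_F",
    "TRIAL_CV_L",
]

#: dose grids used in the recordings the generator emulates (log10 ng)
ORN_DOSES = (-1.0, 0.0, 1.0, 2.0, 3.0, 4.0)
PN_DOSES = (-3.0, -2.0, -1.0, 0.0, 1.0)

#: control (solvent / clean air) raw response rates, mean and SD in AP/s
CONTROL_F_RAW = {"ORN": (15.0, 10.0), "PN": (59.0, 28.0)}

#: latency law (mean, SD in ms) of the control transient, comparable to
#: each class's mid-range pheromone latency
CONTROL_LATENCY = {"ORN": (150.0, 40.0), "PN": (120.0, 30.0)}

#: within-neuron trial-to-trial (irregularity) CVs of rate and latency
TRIAL_CV_F = 0.16
TRIAL_CV_L = 0.34


def _build_model(
    medians: dict[str, float],
    sds: dict[str, float],
    correlations: dict[tuple[str, str], float],
    **kwargs,
) -> PopulationModel:
    """Assemble (M, Sigma) from natural-scale medians plus SDs/correlations
    expressed on the internal scale (log scale for n and lam)."""
    med = np.array([medians[p] for p in PARAM_FIELDS], dtype=float)
    M = forward_transform(med)
    sd = np.array([sds[p] for p in PARAM_FIELDS], dtype=float)
    corr = np.eye(6)
    index = {p: i for i, p in enumerate(PARAM_FIELDS)}
    for (a, b), r in correlations.items():
        corr[index[a], index[b]] = corr[index[b], index[a]] = r
    Sigma = corr * np.outer(sd, sd)
    return PopulationModel(M=M, Sigma=Sigma, **kwargs)


def default_orn_model(N: int = 7000, spont_total_ap_s: float | None = None) -> PopulationModel:
    """Reconstructed pheromone-sensitive ORN population.

    Median ED50 of 1.35 log ng puts the median threshold dose C_0 at
    -0.50 log ng; the latency line (150 - 28 C, floored at 60 ms) reproduces
    the published median maximum latency (164 ms) and latency range (104 ms).
    """
    medians = {"F_M": 163.0, "C_half": 1.35, "n": 0.81,
               "L_0": 150.0, "lam": 28.0, "L_m": 60.0}
    # SDs on internal scale: log-scale spreads for n and lam
    # the n-spread is constrained by the flat population PSTH at doses
    # far below threshold: wider spreads leak shallow-slope responses there
    sds = {"F_M": 35.0, "C_half": 0.66, "n": 0.20,
           "L_0": 60.0, "lam": 0.35, "L_m": 25.0}
    # only the three significantly correlated parameter pairs are non-zero
    correlations = {("C_half", "L_0"): 0.40,
                    ("L_0", "lam"): 0.50,
                    ("L_0", "L_m"): 0.50}
    return _build_model(
        medians, sds, correlations,
        N=N, spont_lognorm=(1.23, 0.71),
        spont_total_ap_s=spont_total_ap_s, label="ORN",
    )


def default_pn_model(N: int = 30) -> PopulationModel:
    """Reconstructed projection-neuron population.

    The 2.7 log-unit ED50 shift relative to the default ORN model encodes the
    ~500-fold sensitivity gain; the latency line (58 - 18.2 C, floored at
    43 ms) gives the published median maximum latency 107 ms, range 64 ms and
    an ORN-to-PN latency-transfer slope of 18.2/28 = 0.65.
    """
    medians = {"F_M": 62.0, "C_half": -1.35, "n": 0.79,
               "L_0": 58.0, "lam": 18.2, "L_m": 43.0}
    sds = {"F_M": 25.0, "C_half": 0.70, "n": 0.25,
           "L_0": 30.0, "lam": 0.40, "L_m": 15.0}
    correlations = {("C_half", "n"): -0.45,
                    ("L_0", "lam"): 0.50,
                    ("L_0", "L_m"): 0.50}
    return _build_model(
        medians, sds, correlations,
        N=N, spont_lognorm=(2.08, 0.71), label="PN",
    )


def default_noise_design() -> NoiseDesign:
    """Stimulus-delivery noise measured with a photoionisation detector."""
    return NoiseDesign()
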