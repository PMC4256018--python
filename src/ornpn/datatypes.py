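"""Core containers shared by every stage of the pipeline.

Conventions used throughout the package:

* time is in milliseconds, with the opening of the stimulus valve at t = 0;
* firing rates are in action potentials per second (AP/s);
* doses ``C`` are decimal logarithms of the pheromone load in nanograms;
* the six-parameter description of a neuron couples a Hill dose-firing-rate
  curve (``F_M``, ``C_half``, ``n``) with a floored dose-latency line
  (``L_0``, ``lam``, ``L_m``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PARAM_FIELDS",
    "LOG_PARAMS",
    "StimulusEvent",
    "SpikeTrain",
    "NeuronParamVector",
    "PopulationModel",
    "NoiseDesign",
]

#: order of the six parameters inside mean vectors / covariance matrices
PARAM_FIELDS = ("F_M", "C_half", "n", "L_0", "lam", "L_m")

#: parameters stored on natural-log scale inside (M, Sigma) because their
#: population marginals are lognormal
LOG_PARAMS = ("n", "lam")

_LOG_IDX = tuple(PARAM_FIELDS.index(p) for p in LOG_PARAMS)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus delivery: a pheromone puff or a control (solvent/air) puff.

    ``transport_time_ms`` is the travel time of the odour from the valve to
    the antenna (mean 180 ms, SD ~13 ms in the recording setup this package
    emulates); latencies are referenced to its mean.
    """

    dose_log_ng: float | None
    valve_open_ms: float = 0.0
    duration_ms: float = 200.0
    transport_time_ms: float = 180.0
    is_control: bool = False
    cartridge_id: str | None = None

    def __post_init__(self) -> None:
        if not self.duration_ms > 0:
            raise ValueError(f"duration_ms must be > 0, got {self.duration_ms}")
        if not self.transport_time_ms > 0:
            raise ValueError(
                f"transport_time_ms must be > 0, got {self.transport_time_ms}"
            )
        if self.is_control:
            if self.dose_log_ng is not None:
                raise ValueError("control events carry no dose")
        else:
            if self.dose_log_ng is None or not math.isfinite(self.dose_log_ng):
                raise ValueError("evoked events need a finite dose_log_ng")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms, relative to valve opening) from one trial."""

    neuron_id: str
    trial_id: str
    stimulus: StimulusEvent | None
    spikes_ms: np.ndarray
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes_ms, dtype=float)
        object.__setattr__(self, "spikes_ms", spikes)
        if spikes.ndim != 1:
            raise ValueError("spikes_ms must be one-dimensional")
        if spikes.size and np.any(np.diff(spikes) <= 0):
            raise ValueError("spike times must be strictly increasing")
        lo, hi = self.window_ms
        if not lo < hi:
            raise ValueError(f"empty recording window {self.window_ms}")
        if spikes.size and (spikes[0] < lo or spikes[-1] > hi):
            raise ValueError("spikes fall outside the recording window")
        if self.stimulus is not None and not (lo <= 0.0 <= hi):
            raise ValueError("evoked trains must include t = 0 in their window")

    @property
    def n_spikes(self) -> int:
        return int(self.spikes_ms.size)

    def duration_s(self) -> float:
        lo, hi = self.window_ms
        return (hi - lo) / 1000.0


@dataclass(frozen=True)
class NeuronParamVector:
    """Six-parameter description of one neuron's dose-response behaviour.

    ``F_M`` maximum firing rate (AP/s); ``C_half`` ED50 (log ng); ``n`` Hill
    coefficient; ``L_0`` latency at C = 0 (ms); ``lam`` latency decrease per
    log unit of dose (ms); ``L_m`` minimum latency (ms).  ``L_m <= L_0`` is
    not required: the floor only applies where the line dips below it.
    """

    F_M: float
    C_half: float
    n: float
    L_0: float
    lam: float
    L_m: float

    def __post_init__(self) -> None:
        if not self.F_M > 0:
            raise ValueError(f"F_M must be > 0, got {self.F_M}")
        if not self.n > 0:
            raise ValueError(f"Hill coefficient n must be > 0, got {self.n}")
        if self.lam < 0:
            raise ValueError(f"latency slope lam must be >= 0, got {self.lam}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "NeuronParamVector":
        return cls(**dict(zip(PARAM_FIELDS, map(float, values))))


def _check_covariance(Sigma: np.ndarray) -> np.ndarray:
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (6, 6):
        raise ValueError(f"Sigma must be 6x6, got shape {Sigma.shape}")
    if not np.allclose(Sigma, Sigma.T, atol=1e-10):
        raise ValueError("Sigma must be symmetric")
    eigvals = np.linalg.eigvalsh(Sigma)
    tol = -1e-10 * max(1.0, float(eigvals.max(initial=0.0)))
    if eigvals.min() < tol:
        raise ValueError(
            "Sigma is not positive semi-definite: "
            f"smallest eigenvalue {eigvals.min():.6g}"
        )
    return Sigma


@dataclass(frozen=True)
class PopulationModel:
    """Multinormal generator of whole neuron populations.

    ``M`` and ``Sigma`` describe the joint distribution of the six
    parameters, with ``n`` and ``lam`` on natural-log scale (their marginals
    are lognormal; all others Gaussian).  ``spont_lognorm`` holds (mu, sigma)
    of the natural log of the spontaneous firing rate.  ``spont_total_ap_s``
    optionally rescales spontaneous draws so that the expected *population*
    total equals a fixed value (the "27 000 AP/s" convention); set to None to
    use the raw lognormal law.
    """

    M: np.ndarray
    Sigma: np.ndarray
    N: int = 7000
    spont_lognorm: tuple[float, float] = (1.23, 0.71)
    F_0: float = 5.0
    spont_total_ap_s: float | None = None
    label: str = "ORN"

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.shape != (6,):
            raise ValueError(f"M must have 6 entries, got shape {M.shape}")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "Sigma", _check_covariance(self.Sigma))
        if self.N < 1:
            raise ValueError("population size N must be >= 1")
        if self.spont_lognorm[1] < 0:
            raise ValueError("spontaneous lognormal sigma must be >= 0")

    # -- transforms between internal (log) and natural parameter scales ----
    def param_quantiles(self, q: float) -> NeuronParamVector:
        """Marginal quantile-q parameter vector on the natural scale."""
        z = stats.norm.ppf(q)
        sd = np.sqrt(np.diag(self.Sigma))
        vals = self.M + z * sd
        vals = back_transform(vals)
        return NeuronParamVector.from_array(vals)

    def median_params(self) -> NeuronParamVector:
        return self.param_quantiles(0.5)

    def spont_mean_rate(self) -> float:
        """Expected spontaneous rate per neuron (AP/s) under the model."""
        if self.spont_total_ap_s is not None:
            return self.spont_total_ap_s / self.N
        mu, sigma = self.spont_lognorm
        return float(np.exp(mu + sigma**2 / 2.0))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "M": self.M.tolist(),
            "Sigma": self.Sigma.tolist(),
            "N": self.N,
            "spont_lognorm": list(self.spont_lognorm),
            "F_0": self.F_0,
            "spont_total_ap_s": self.spont_total_ap_s,
            "label": self.label,
            "param_order": list(PARAM_FIELDS),
            "log_scale_params": list(LOG_PARAMS),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            M=np.asarray(d["M"], dtype=float),
            Sigma=np.asarray(d["Sigma"], dtype=float),
            N=int(d.get("N", 7000)),
            spont_lognorm=tuple(d.get("spont_lognorm", (1.23, 0.71))),
            F_0=float(d.get("F_0", 5.0)),
            spont_total_ap_s=d.get("spont_total_ap_s"),
            label=d.get("label", "ORN"),
        )

    @classmethod
    def from_json(cls, path) -> "PopulationModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def with_N(self, N: int) -> "PopulationModel":
        return replace(self, N=N)


def back_transform(values: np.ndarray) -> np.ndarray:
    """Exponentiate the log-scale coordinates (n, lam) of a 6-vector."""
    out = np.array(values, dtype=float, copy=True)
    out[..., list(_LOG_IDX)] = np.exp(out[..., list(_LOG_IDX)])
    return out


def forward_transform(values: np.ndarray) -> np.ndarray:
    """Log-transform the (n, lam) coordinates of a natural-scale 6-vector."""
    out = np.array(values, dtype=float, copy=True)
    out[..., list(_LOG_IDX)] = np.log(out[..., list(_LOG_IDX)])
    return out


@dataclass(frozen=True)
class NoiseDesign:
    """Two-level stimulus noise: irregularity within a cartridge, heterogeneity
    across identically prepared cartridges.

    Defaults follow the photoionisation measurements the analysis assumes:
    onset-time SDs 13.3 ms (heterogeneity) vs 4.43 ms (irregularity) and
    amplitude CVs 0.195 vs 0.05, estimated from 10 series of 14 repetitions.
    """

    n_series: int = 10
    n_reps: int = 14
    onset_heterogeneity_sd_ms: float = 13.3
    onset_irregularity_sd_ms: float = 4.43
    amp_heterogeneity_cv: float = 0.195
    amp_irregularity_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_series < 1 or self.n_reps < 1:
            raise ValueError("n_series and n_reps must be >= 1")
        for name in (
            "onset_heterogeneity_sd_ms",
            "onset_irregularity_sd_ms",
            "amp_heterogeneity_cv",
            "amp_irregularity_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_series * self.n_reps
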