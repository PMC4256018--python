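"""Summed output of the heterogeneous ORN population converging on PNs.

Several thousand first-order neurons sharing one receptor type converge
onto each projection neuron.  Each simulated neuron draws its six
parameters from the population model, responds to a dose with a regular
train (latency from its dose-latency line, interspike interval 1/F from its
Hill curve) on top of its spontaneous background, and the population PSTH
is the 10-ms-binned total spike count.  Detection requires the summed rate
to exceed the spontaneous baseline B by r standard deviations of its
Poisson-like fluctuations: threshold = B + r * sqrt(B).

Per-neuron randomness uses one substream per neuron spawned from the master
seed, so enlarging N leaves the first neurons' draws unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import PARAM_FIELDS, NeuronParamVector, PopulationModel
from .doseresponse import hill_value, latency_value
from .synthetic import _cholesky, _draw_param_vector

__all__ = [
    "PSTH",
    "DetectionSetting",
    "simulate_population_response",
    "simulate_population_spontaneous",
    "detection_threshold_rate",
    "threshold_dose",
    "fraction_faster_than",
    "typical_neuron",
    "rise_time_ms",
]

_LAT_IDX = [PARAM_FIELDS.index(p) for p in ("L_0", "lam", "L_m")]


@dataclass(frozen=True)
class PSTH:
    """Population peristimulus time histogram: total spikes per bin."""

    bin_edges_ms: np.ndarray
    counts: np.ndarray
    n_neurons: int
    dose: float | None

    def __post_init__(self) -> None:
        if self.counts.size != self.bin_edges_ms.size - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())

    def rate_ap_s(self) -> np.ndarray:
        """Summed population rate per bin in AP/s."""
        return self.counts * (1000.0 / self.bin_ms)

    def peak_count(self) -> int:
        return int(self.counts.max(initial=0))

    def plot(self, ax=None, **kwargs):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.stairs(self.counts, self.bin_edges_ms, **kwargs)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel(f"spikes / {self.bin_ms:.0f} ms")
        return ax


@dataclass(frozen=True)
class DetectionSetting:
    """Baseline population rate B (AP/s) and signal-to-noise ratio r."""

    baseline_total_ap_s: float = 27000.0
    r: float = 3.0

    def __post_init__(self) -> None:
        if self.baseline_total_ap_s < 0 or self.r < 0:
            raise ValueError("baseline and r must be >= 0")


def detection_threshold_rate(setting: DetectionSetting) -> float:
    """Population rate a stimulus must exceed to be detectable: B + r sqrt(B)."""
    B = setting.baseline_total_ap_s
    return float(B + setting.r * math.sqrt(B))


def _spont_scale(model: PopulationModel) -> float:
    """Multiplier applied to lognormal spontaneous draws under the
    fixed-population-total convention."""
    if model.spont_total_ap_s is None:
        return 1.0
    mu, sigma = model.spont_lognorm
    lognorm_mean = math.exp(mu + sigma**2 / 2.0)
    return model.spont_total_ap_s / (model.N * lognorm_mean)


def _neuron_spikes(params: NeuronParamVector, dose: float | None,
                   spont_rate: float, duration_ms: float,
                   rng: np.random.Generator, f_floor: float = 0.1) -> list[np.ndarray]:
    parts = []
    if dose is not None:
        F = hill_value(params.F_M, params.C_half, params.n, dose)
        L = latency_value(params.L_0, params.lam, params.L_m, dose)
        t0 = 180.0 + L
        if F >= f_floor and t0 < duration_ms:
            isi = 1000.0 / F
            expected = (duration_ms - t0) / isi
            if expected < 1.0:
                # sparse regime: a deterministic onset spike would overstate
                # the rate; emit it with the train's expected occupancy
                if rng.random() < expected:
                    parts.append(np.array([t0]))
            else:
                cnt = int(math.floor((duration_ms - t0) / isi - 1e-12)) + 1
                parts.append(t0 + isi * np.arange(cnt))
    if spont_rate > 0:
        isi = 1000.0 / spont_rate
        phase = rng.uniform(0.0, isi)
        cnt = int(math.floor((duration_ms - phase) / isi)) + 1
        parts.append(phase + isi * np.arange(cnt))
    return parts


def _simulate(model: PopulationModel, dose: float | None, duration_ms: float,
              bin_ms: float, seed: int) -> PSTH:
    chol = _cholesky(model)
    scale = _spont_scale(model)
    mu_sp, sd_sp = model.spont_lognorm
    children = np.random.SeedSequence(seed).spawn(model.N)
    edges = np.arange(0.0, duration_ms + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1, dtype=int)
    for child in children:
        rng = np.random.Generator(np.random.Philox(child))
        params = _draw_param_vector(model, chol, rng)
        spont = scale * math.exp(rng.normal(mu_sp, sd_sp))
        for arr in _neuron_spikes(params, dose, spont, duration_ms, rng):
            c, _ = np.histogram(arr, bins=edges)
            counts += c
    return PSTH(bin_edges_ms=edges, counts=counts, n_neurons=model.N,
                dose=dose)


def simulate_population_response(model: PopulationModel, dose: float,
                                 duration_ms: float = 1000.0,
                                 bin_ms: float = 10.0,
                                 seed: int = 0) -> PSTH:
    """PSTH of the whole population responding at one dose (evoked trains
    superposed additively on spontaneous background)."""
    return _simulate(model, dose, duration_ms, bin_ms, seed)


def simulate_population_spontaneous(model: PopulationModel,
                                    duration_ms: float = 1000.0,
                                    bin_ms: float = 10.0,
                                    seed: int = 0) -> PSTH:
    """PSTH of the unstimulated population (lognormal rates, regular trains
    with random phase)."""
    return _simulate(model, None, duration_ms, bin_ms, seed)


def rise_time_ms(psth: PSTH, frac: float = 0.95,
                 baseline_count: float = 0.0,
                 origin_ms: float = 180.0) -> float:
    """Time (ms after ``origin_ms``, default stimulus arrival) at which the
    summed rate first reaches ``frac`` of its plateau above baseline.

    Under the sustained regular-train model the population rate rises while
    neurons are recruited in order of latency and then stays on a plateau,
    so the end of the rise marks the response maximum.
    """
    excess = psth.counts.astype(float) - baseline_count
    plateau = np.quantile(excess, 0.9)
    if plateau <= 0:
        return float("nan")
    idx = np.flatnonzero(excess >= frac * plateau)
    if idx.size == 0:
        return float("nan")
    t = psth.bin_edges_ms[idx[0]] + psth.bin_ms / 2.0
    return float(t - origin_ms)


def threshold_dose(model: PopulationModel, setting: DetectionSetting,
                   dose_grid, seed: int = 0, n_seeds: int = 10,
                   duration_ms: float = 800.0, bin_ms: float = 10.0):
    """Lowest dose on the grid whose mean peak bin count crosses the
    detection threshold.

    The threshold rate B + r sqrt(B) (AP/s) converts to a per-bin count; the
    peak count is Monte-Carlo averaged over ``n_seeds`` independent
    populations.  Returns (dose, crossed); ``crossed`` is False when the
    grid never reaches threshold (dose is then nan).
    """
    # Near threshold the summed response is a transient bump (the onset
    # spikes of weakly driven neurons, spread over the latency
    # distribution), so the statistic is the peak of a 100-ms windowed
    # mean of the ensemble-averaged PSTH, in excess of the ensemble's own
    # pre-arrival baseline.  The averaging is what keeps the small
    # r*sqrt(B) margin resolvable against single-bin noise.
    thr_excess = setting.r * math.sqrt(setting.baseline_total_ap_s) * bin_ms / 1000.0
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    width = max(int(round(100.0 / bin_ms)), 1)
    kernel = np.ones(width) / width
    for dose in sorted(np.asarray(dose_grid, dtype=float)):
        psths = [simulate_population_response(model, dose, duration_ms,
                                              bin_ms, seed=int(base + 97 * k))
                 for k in range(n_seeds)]
        mean_counts = np.mean([p.counts for p in psths], axis=0)
        centers = psths[0].bin_edges_ms[:-1] + bin_ms / 2.0
        pre = centers < 180.0
        baseline = float(mean_counts[pre].mean()) if pre.any() else 0.0
        windowed = np.convolve(mean_counts, kernel, mode="valid")
        if float(windowed.max()) - baseline >= thr_excess:
            return float(dose), True
    return float("nan"), False


def typical_neuron(model: PopulationModel, quantile: float = 0.5) -> NeuronParamVector:
    """Neuron whose six parameters each sit at the same marginal quantile
    (lognormal parameters back-transformed)."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    return model.param_quantiles(quantile)


def _latency_block(model: PopulationModel):
    idx = np.asarray(_LAT_IDX)
    m = model.M[idx]
    S = model.Sigma[np.ix_(idx, idx)]
    return m, S  # order (L_0, ln lam, L_m)


def fraction_faster_than(model: PopulationModel, dose: float, L_ref: float,
                         mode: str = "analytic", seed: int = 0,
                         n_draws: int = 100_000) -> float:
    """P[L(dose) <= L_ref] over the parameter distribution.

    With L(C) = max(L_0 - lam C, L_m) the event requires both the line and
    the floor to sit at or below L_ref.  ``analytic`` integrates over the
    lognormal lam by Gauss-Hermite quadrature, using the conditional
    bivariate normal law of (L_0, L_m); ``montecarlo`` draws parameter
    vectors directly.  The two modes agree within Monte-Carlo error.
    """
    if not np.isfinite(L_ref):
        return 1.0 if L_ref > 0 else 0.0
    m, S = _latency_block(model)
    if mode == "montecarlo":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(m, S, size=n_draws,
                                        method="cholesky" if _is_pd(S) else "eigh")
        L0, lam, Lm = draws[:, 0], np.exp(draws[:, 1]), draws[:, 2]
        L = np.maximum(L0 - lam * dose, Lm)
        return float(np.mean(L <= L_ref))
    if mode != "analytic":
        raise ValueError(f"unknown mode {mode!r}")
    mu_v, var_v = m[1], S[1, 1]
    if var_v <= 1e-14:
        lam = math.exp(mu_v)
        mean2 = np.array([m[0], m[2]])
        cov2 = S[np.ix_([0, 2], [0, 2])]
        return _bivariate_below(mean2, cov2,
                                np.array([L_ref + lam * dose, L_ref]))
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    total = 0.0
    sd_v = math.sqrt(var_v)
    cross = S[[0, 2], 1] / var_v  # regression of (L_0, L_m) on ln lam
    cond_cov = S[np.ix_([0, 2], [0, 2])] - np.outer(S[[0, 2], 1], S[[0, 2], 1]) / var_v
    for z, w in zip(nodes, weights):
        v = mu_v + sd_v * z
        lam = math.exp(v)
        cond_mean = np.array([m[0], m[2]]) + cross * (v - mu_v)
        p = _bivariate_below(cond_mean, cond_cov,
                             np.array([L_ref + lam * dose, L_ref]))
        total += w * p
    return float(total / math.sqrt(2.0 * math.pi))


def _is_pd(S: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(S)
        return True
    except np.linalg.LinAlgError:
        return False


def _bivariate_below(mean: np.ndarray, cov: np.ndarray, upper: np.ndarray) -> float:
    """P[X1 <= u1, X2 <= u2] for a bivariate normal, robust to degenerate
    (zero-variance) coordinates."""
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    active = sd > 1e-10
    if not active.any():
        return float(np.all(mean <= upper))
    if active.sum() == 1:
        i = int(np.flatnonzero(active)[0])
        j = 1 - i
        if mean[j] > upper[j]:
            return 0.0
        return float(stats.norm.cdf(upper[i], loc=mean[i], scale=sd[i]))
    rho = cov[0, 1] / (sd[0] * sd[1])
    rho = float(np.clip(rho, -0.9999, 0.9999))
    z = (upper - mean) / sd
    return float(stats.multivariate_normal.cdf(
        z, mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]))
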