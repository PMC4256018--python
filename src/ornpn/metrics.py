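"""Spike-train response metrics.

The instantaneous firing rate f(t) is a Gaussian-kernel estimate (SD 50 ms,
unit area per spike in seconds, so f is in AP/s).  From it come the raw
response rate F_raw (height of the first qualifying peak after the
stimulus), a bump-counting significance test against the neuron's own
spontaneous activity, the response time T (first attributable spike after
valve opening), the latency L = T - T_t relative to the mean odour
transport time T_t = 180 ms, and the control-corrected rate F = F_raw - F_c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import SpikeTrain, StimulusEvent

__all__ = [
    "RateFunction",
    "ResponseMeasure",
    "estimate_rate",
    "peak_rate",
    "bump_heights",
    "significance_test",
    "response_time",
    "latency",
    "control_mean",
    "pool_controls",
    "spontaneous_rate",
    "measure_response",
    "DEFAULT_TRANSPORT_MS",
    "TRANSPORT_SD_MS",
]

DEFAULT_TRANSPORT_MS = 180.0
TRANSPORT_SD_MS = 13.0
#: default window searched for the response peak, relative to valve opening
RESPONSE_WINDOW_MS = (DEFAULT_TRANSPORT_MS - 40.0, DEFAULT_TRANSPORT_MS + 1000.0)


@dataclass(frozen=True)
class RateFunction:
    """Kernel firing-rate estimate on a uniform time grid."""

    grid_ms: np.ndarray
    f_ap_s: np.ndarray
    kernel_sd_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.grid_ms.shape != self.f_ap_s.shape:
            raise ValueError("grid and values must align")

    @property
    def step_ms(self) -> float:
        return float(self.grid_ms[1] - self.grid_ms[0]) if self.grid_ms.size > 1 else 1.0

    def integral_spikes(self) -> float:
        """Area under f in units of spikes (f is AP/s, grid in ms)."""
        return float(np.trapezoid(self.f_ap_s, self.grid_ms) / 1000.0)

    def restrict(self, t_lo: float, t_hi: float) -> "RateFunction":
        m = (self.grid_ms >= t_lo) & (self.grid_ms <= t_hi)
        return RateFunction(self.grid_ms[m], self.f_ap_s[m], self.kernel_sd_ms)


@dataclass
class ResponseMeasure:
    """Per-trial response variables."""

    neuron_id: str
    trial_id: str
    dose_log_ng: float
    F_raw: float
    F_c: float
    T_ms: float
    L_ms: float
    significant: bool

    @property
    def F(self) -> float:
        return self.F_raw - self.F_c


def estimate_rate(train: SpikeTrain, kernel_sd_ms: float = 50.0,
                  grid_step_ms: float = 1.0) -> RateFunction:
    """Gaussian-kernel rate estimate: f(t) = sum over spikes of
    N(t - t_spike; SD) with unit area per spike (in seconds), truncated at
    +-4 SD.  An empty train gives the zero function."""
    lo, hi = train.window_ms
    grid = np.arange(lo, hi + grid_step_ms / 2, grid_step_ms)
    if train.n_spikes == 0:
        return RateFunction(grid, np.zeros_like(grid), kernel_sd_ms)
    # bin the spikes on the grid, then convolve with the sampled kernel
    edges = np.concatenate([grid - grid_step_ms / 2, [grid[-1] + grid_step_ms / 2]])
    counts, _ = np.histogram(train.spikes_ms, bins=edges)
    half = int(np.ceil(4.0 * kernel_sd_ms / grid_step_ms))
    offsets = np.arange(-half, half + 1) * grid_step_ms
    kernel = np.exp(-0.5 * (offsets / kernel_sd_ms) ** 2)
    kernel *= 1000.0 / (kernel_sd_ms * np.sqrt(2.0 * np.pi))  # density per second
    f = np.convolve(counts.astype(float), kernel, mode="same")
    return RateFunction(grid, f, kernel_sd_ms)


def _local_max_indices(f: np.ndarray) -> np.ndarray:
    """Strict local maxima; a plateau contributes its first grid point."""
    if f.size < 3:
        return np.empty(0, dtype=int)
    rising = f[1:-1] > f[:-2]
    not_below_next = f[1:-1] >= f[2:]
    cand = np.flatnonzero(rising & not_below_next) + 1
    # keep a plateau point only if the plateau eventually falls
    keep = []
    for i in cand:
        j = i
        while j + 1 < f.size and f[j + 1] == f[i]:
            j += 1
        if j + 1 >= f.size or f[j + 1] < f[i]:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def peak_rate(rate: RateFunction, response_window_ms=RESPONSE_WINDOW_MS,
              mode: str = "first"):
    """Response peak of f inside the window, returned as (F_raw, peak_time).

    ``mode="first"`` returns the first local maximum whose height exceeds
    the pre-stimulus mean rate (the excitation-phase peak of a multiphasic
    response, not the rebound), falling back to the global maximum in the
    window.  ``mode="global"`` returns the global maximum directly - the
    right choice for monophasic sustained responses, where ripples on the
    rising plateau would otherwise masquerade as early peaks."""
    t_lo, t_hi = response_window_ms
    mask = (rate.grid_ms >= t_lo) & (rate.grid_ms <= t_hi)
    if not mask.any():
        raise ValueError("response window lies outside the rate grid")
    f_win = rate.f_ap_s[mask]
    t_win = rate.grid_ms[mask]
    if mode == "first":
        pre = rate.f_ap_s[rate.grid_ms < 0]
        pre_mean = float(pre.mean()) if pre.size else 0.0
        for i in _local_max_indices(f_win):
            if f_win[i] > pre_mean:
                return float(f_win[i]), float(t_win[i])
    elif mode != "global":
        raise ValueError(f"unknown peak mode {mode!r}")
    i = int(np.argmax(f_win))
    return float(f_win[i]), float(t_win[i])


def bump_heights(spont_rate: RateFunction) -> np.ndarray:
    """Heights of the bumps (strict local maxima) of a spontaneous-activity
    rate function."""
    idx = _local_max_indices(spont_rate.f_ap_s)
    return spont_rate.f_ap_s[idx]


def significance_test(F_raw: float, spont_rate: RateFunction,
                      level: float = 0.05) -> bool:
    """A response is significant when fewer than ``level`` of the
    spontaneous bumps reach F_raw.  With no bumps at all (silent neuron),
    any positive F_raw is significant."""
    heights = bump_heights(spont_rate)
    if heights.size == 0:
        return F_raw > 0
    frac = np.count_nonzero(heights >= F_raw) / heights.size
    return bool(frac < level)


def response_time(train: SpikeTrain, stim: StimulusEvent | None = None,
                  earliest_ms: float | None = None,
                  burst_isi_ms: float | None = None) -> float:
    """Time of the first response-attributable spike after valve opening.

    Spikes earlier than ``T_t - 3 * 13`` ms cannot plausibly be evoked
    (odour not yet arrived) and are skipped - a conservative rule that can
    only lengthen T.  With ``burst_isi_ms`` set, a candidate must in
    addition start a run of spikes with gaps within that interval (the
    response is a burst, an isolated spontaneous spike is not).  Returns
    nan when no attributable spike exists."""
    stim = stim if stim is not None else train.stimulus
    t_t = stim.transport_time_ms if stim is not None else DEFAULT_TRANSPORT_MS
    valve = stim.valve_open_ms if stim is not None else 0.0
    if earliest_ms is None:
        earliest_ms = t_t - 3.0 * TRANSPORT_SD_MS
    spikes = train.spikes_ms
    sel = (spikes > valve) & (spikes >= earliest_ms)
    cand = spikes[sel]
    if cand.size == 0:
        return float("nan")
    if burst_isi_ms is not None:
        idx = np.flatnonzero(sel)
        for i in idx:
            gaps = np.diff(spikes[i:i + 3])
            if gaps.size and np.all(gaps <= burst_isi_ms):
                return float(spikes[i])
        return float("nan")  # no burst-like onset: response time undefined
    return float(cand[0])


def latency(T_ms: float, T_t: float = DEFAULT_TRANSPORT_MS) -> float:
    """L = T - T_t; negative values are legitimate (short transport times)."""
    return T_ms - T_t


def attribute_response_time(rate: RateFunction, spikes_ms: np.ndarray,
                            F_raw: float, F_c: float,
                            earliest_ms: float | None = None,
                            burst_factor: float = 2.0) -> float:
    """Onset-anchored response-time attribution.

    For a rate step of height h smoothed by a Gaussian kernel, f crosses
    baseline + h/2 exactly at the step time, so the half-rise crossing of
    the kernel estimate locates the response onset to within the noise.
    The first spike near that crossing which starts a burst (following
    interspike gaps within ``burst_factor`` evoked intervals) is the
    response time; nan when nothing qualifies."""
    if earliest_ms is None:
        earliest_ms = DEFAULT_TRANSPORT_MS - 3.0 * TRANSPORT_SD_MS
    h = max(F_raw - F_c, 10.0)
    level = F_c + 0.5 * h
    m = rate.grid_ms >= earliest_ms
    above = m & (rate.f_ap_s >= level)
    if not above.any():
        return float("nan")
    t_on = float(rate.grid_ms[above][0])
    lo, hi = t_on - 70.0, t_on + 150.0
    sel = (spikes_ms >= max(lo, earliest_ms)) & (spikes_ms <= hi)
    idx = np.flatnonzero(sel)
    thr = burst_factor * 1000.0 / h
    for i in idx:
        gaps = np.diff(spikes_ms[i:i + 3])
        if gaps.size and np.all(gaps <= thr):
            return float(spikes_ms[i])
    return float("nan")


def pool_controls(a, b, level: float = 0.05):
    """Pool two control samples (e.g. hexane and pure air) unless a
    two-sample KS test rejects their equality.  Returns (values, pooled)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return np.concatenate([a, b]), True
    p = stats.ks_2samp(a, b).pvalue
    if p >= level:
        return np.concatenate([a, b]), True
    return a, False


def control_mean(control_f_raw) -> float:
    """Per-neuron control rate F_c: mean of raw control responses."""
    vals = np.asarray(control_f_raw, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("control_mean needs at least one control trial")
    return float(vals.mean())


def spontaneous_rate(train: SpikeTrain) -> float:
    """Mean spontaneous rate as the slope (AP/s) of the regression of
    cumulative spike count on spike time."""
    t = train.spikes_ms
    if t.size < 2:
        if t.size < 2:
            warnings.warn("fewer than 2 spikes: spontaneous rate set to 0",
                          stacklevel=2)
        return 0.0
    counts = np.arange(1, t.size + 1, dtype=float)
    slope = np.polyfit(t / 1000.0, counts, 1)[0]
    return float(slope)


def measure_response(train: SpikeTrain, F_c: float,
                     kernel_sd_ms: float = 50.0,
                     response_window_ms=RESPONSE_WINDOW_MS,
                     peak_mode: str = "global") -> ResponseMeasure:
    """Full per-trial measurement: kernel rate, peak F_raw, significance
    against the trial's own pre-stimulus activity, response time and
    latency.  The default global-maximum peak suits monophasic responses;
    use ``peak_mode="first"`` for multiphasic shapes with rebounds."""
    rate = estimate_rate(train, kernel_sd_ms=kernel_sd_ms)
    F_raw, _ = peak_rate(rate, response_window_ms, mode=peak_mode)
    spont_part = rate.restrict(train.window_ms[0], 0.0)
    significant = significance_test(F_raw, spont_part)
    T = attribute_response_time(rate, train.spikes_ms, F_raw, F_c)
    L = latency(T, DEFAULT_TRANSPORT_MS) if np.isfinite(T) else float("nan")
    stim = train.stimulus
    dose = stim.dose_log_ng if (stim is not None and stim.dose_log_ng is not None) else float("nan")
    return ResponseMeasure(neuron_id=train.neuron_id, trial_id=train.trial_id,
                           dose_log_ng=dose, F_raw=F_raw, F_c=F_c,
                           T_ms=T, L_ms=L, significant=significant)
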