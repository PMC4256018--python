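"""Dose-response curves: Hill fits for firing rate, floored lines for latency.

The firing rate of a neuron at dose ``C`` (log10 ng) follows a Hill function

    F(C) = F_M / (1 + 10^{n (C_1/2 - C)})

and its first-spike latency a linearly decreasing function with a floor

    L(C) = max(L_0 - lam * C, L_m).

Three characteristics derive from the Hill parameters with the response
criterion F_0 (default 5 AP/s): the threshold dose C_0 where F rises above
F_0, the saturation dose C_s where F reaches F_M - F_0, and the dynamic
range Delta_C = C_s - C_0.  In closed form

    C_0 = C_1/2 - (1/n) log10(F_M/F_0 - 1)
    C_s = C_1/2 + (1/n) log10(F_M/F_0 - 1)
    Delta_C = (2/n) log10(F_M/F_0 - 1)

For latency, the maximum latency at threshold is L_M = L_0 - lam * C_0 and
the latency range Delta_L = L_M - L_m.

Fitting follows the estimation conventions of statsmodels: ``HillModel`` /
``LatencyModel`` are built from data, ``fit()`` returns a results object
carrying estimates, standard errors, residuals and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import NeuronParamVector

__all__ = [
    "hill_value",
    "latency_value",
    "HillModel",
    "HillResults",
    "LatencyModel",
    "LatencyResults",
    "fit_hill",
    "fit_latency_line",
    "derive_characteristics",
    "derive_latency_characteristics",
]

_MAX_EXP = 300.0  # clip 10^x exponents to avoid overflow


def hill_value(F_M, C_half, n, C):
    """Firing rate (AP/s) of the Hill dose-response curve at dose(s) C."""
    C = np.asarray(C, dtype=float)
    expo = np.clip(n * (C_half - C), -_MAX_EXP, _MAX_EXP)
    out = F_M / (1.0 + 10.0**expo)
    return out if out.ndim else float(out)


def latency_value(L_0, lam, L_m, C):
    """First-spike latency (ms): decreasing line in dose, floored at L_m."""
    C = np.asarray(C, dtype=float)
    out = np.maximum(L_0 - lam * C, L_m)
    return out if out.ndim else float(out)


def derive_characteristics(F_M: float, C_half: float, n: float, F_0: float = 5.0):
    """Threshold dose, saturation dose and dynamic range of a Hill curve.

    Defined only when F_M > 2 F_0 (otherwise the curve never clears both the
    threshold and the saturation criterion); returns (nan, nan, nan) then.
    """
    if not F_M > 2.0 * F_0:
        return float("nan"), float("nan"), float("nan")
    half_width = np.log10(F_M / F_0 - 1.0) / n
    return C_half - half_width, C_half + half_width, 2.0 * half_width


def derive_latency_characteristics(L_0: float, lam: float, L_m: float, C_0: float):
    """Maximum latency at threshold and latency range (L_M, Delta_L)."""
    if not np.isfinite(C_0):
        return float("nan"), float("nan")
    L_M = L_0 - lam * C_0
    return float(L_M), float(L_M - L_m)


# ---------------------------------------------------------------------------
# Hill model
# ---------------------------------------------------------------------------


class HillModel:
    """Nonlinear least-squares Hill fit of firing rate versus log dose.

    Parameters
    ----------
    doses, rates : array-like
        Paired observations; at least 4 pairs spanning >= 2 log units are
        recommended for identifiability.
    F_0 : float
        Response criterion (AP/s) used for the derived characteristics.
    """

    def __init__(self, doses, rates, F_0: float = 5.0):
        self.doses = np.asarray(doses, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.doses.shape != self.rates.shape or self.doses.ndim != 1:
            raise ValueError("doses and rates must be 1-d arrays of equal length")
        if self.doses.size < 3:
            raise ValueError("need at least 3 (dose, rate) pairs")
        self.F_0 = float(F_0)

    def _starts(self):
        """Multistart grid: Hill slopes {0.5, 1, 2} at the median dose plus
        unit slope at the 25% / 75% dose quantiles (5 starts)."""
        qs = np.quantile(self.doses, [0.25, 0.5, 0.75])
        f_top = max(self.rates.max(), 1.0)
        return [
            (f_top, qs[1], 0.5),
            (f_top, qs[1], 1.0),
            (f_top, qs[1], 2.0),
            (f_top, qs[0], 1.0),
            (f_top, qs[2], 1.0),
        ]

    def fit(self) -> "HillResults":
        doses, rates = self.doses, self.rates
        degenerate = np.ptp(rates) <= 1e-12
        lo = (1e-6, doses.min() - 3.0, 0.05)
        hi = (2.0 * max(rates.max(), 1.0), doses.max() + 3.0, 10.0)
        best = None
        if not degenerate:
            for p0 in self._starts():
                p0 = np.clip(p0, lo, hi)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        popt, pcov = curve_fit(
                            lambda C, F_M, C_half, n: hill_value(F_M, C_half, n, C),
                            doses, rates, p0=p0, bounds=(lo, hi), maxfev=20000,
                        )
                except (RuntimeError, ValueError):
                    continue
                rss = float(np.sum((rates - hill_value(*popt, doses)) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, popt, pcov)
        if best is None:
            params = np.array([max(rates.max(), 1.0), np.median(doses), 1.0])
            return HillResults(self, params, np.full((3, 3), np.nan),
                               rss=float(np.sum((rates - rates.mean()) ** 2)),
                               converged=False)
        rss, popt, pcov = best
        return HillResults(self, popt, pcov, rss=rss, converged=True)


@dataclass
class HillResults:
    """Fitted Hill curve with derived dose characteristics."""

    model: HillModel
    params: np.ndarray  # (F_M, C_half, n)
    cov_params: np.ndarray
    rss: float
    converged: bool

    param_names = ("F_M", "C_half", "n")

    @property
    def F_M(self) -> float:
        return float(self.params[0])

    @property
    def C_half(self) -> float:
        return float(self.params[1])

    @property
    def n(self) -> float:
        return float(self.params[2])

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params))

    def predict(self, doses) -> np.ndarray:
        return hill_value(self.F_M, self.C_half, self.n, doses)

    @property
    def resid(self) -> np.ndarray:
        return self.model.rates - self.predict(self.model.doses)

    def characteristics(self):
        """(C_0, C_s, Delta_C) for the model's response criterion F_0."""
        return derive_characteristics(self.F_M, self.C_half, self.n, self.model.F_0)

    @property
    def C_0(self) -> float:
        return self.characteristics()[0]

    @property
    def C_s(self) -> float:
        return self.characteristics()[1]

    @property
    def Delta_C(self) -> float:
        return self.characteristics()[2]

    def summary(self) -> str:
        c0, cs, dc = self.characteristics()
        lines = [
            "Hill dose-response fit",
            "=" * 46,
            f"{'observations':<22}{self.model.doses.size:>12d}",
            f"{'converged':<22}{str(self.converged):>12}",
            f"{'residual SS':<22}{self.rss:>12.4g}",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<10}{est:>12.4g}{se:>12.4g}")
        lines += [
            "-" * 46,
            f"{'C_0 (threshold)':<22}{c0:>12.4g}",
            f"{'C_s (saturation)':<22}{cs:>12.4g}",
            f"{'Delta_C (dyn. range)':<22}{dc:>12.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(self.model.doses.min() - 1, self.model.doses.max() + 1, 200)
        ax.plot(self.model.doses, self.model.rates, "o", **kwargs)
        ax.plot(grid, self.predict(grid), "-")
        ax.set_xlabel("dose C (log ng)")
        ax.set_ylabel("firing rate F (AP/s)")
        return ax


# ---------------------------------------------------------------------------
# Latency model
# ---------------------------------------------------------------------------


class LatencyModel:
    """Least-squares fit of the floored latency line L(C) = max(L_0 - lam C, L_m).

    The floor L_m is the shortest measured latency.  Points sitting on the
    floor at the highest doses would bias the line, so observations within
    ``floor_tol_ms`` (default 5 ms) of the running minimum at the two highest
    doses are excluded from the (L_0, lam) regression.
    """

    def __init__(self, doses, latencies, floor_tol_ms: float = 5.0):
        self.doses = np.asarray(doses, dtype=float)
        self.latencies = np.asarray(latencies, dtype=float)
        if self.doses.shape != self.latencies.shape or self.doses.ndim != 1:
            raise ValueError("doses and latencies must be 1-d arrays of equal length")
        if self.doses.size < 3:
            raise ValueError("need at least 3 (dose, latency) pairs")
        self.floor_tol_ms = float(floor_tol_ms)

    def _regression_mask(self) -> np.ndarray:
        L_m = self.latencies.min()
        top_two = np.unique(self.doses)[-2:]
        on_floor = (np.isin(self.doses, top_two)
                    & (self.latencies <= L_m + self.floor_tol_ms))
        # never drop so many points that the line is unidentifiable
        if (~on_floor).sum() < 2:
            return np.ones_like(on_floor, dtype=bool)
        return ~on_floor

    def fit(self) -> "LatencyResults":
        from scipy.optimize import least_squares

        L_m = float(self.latencies.min())
        # initialise on the explicitly non-floored subset ...
        mask = self._regression_mask()
        x, y = self.doses[mask], self.latencies[mask]
        slope0, intercept0 = np.polyfit(x, y, 1)
        # ... then refine against the floored model, so that points sitting
        # on the floor no longer attenuate the slope
        sol = least_squares(
            lambda p: np.maximum(p[0] - p[1] * self.doses, L_m) - self.latencies,
            x0=[float(intercept0), float(max(-slope0, 1e-3))],
            loss="soft_l1", f_scale=20.0, max_nfev=2000)
        intercept, lam = float(sol.x[0]), float(sol.x[1])
        pred = np.maximum(intercept - lam * self.doses, L_m)
        rss = float(np.sum((self.latencies - pred) ** 2))
        # covariance of (slope, intercept) from the non-floored regime
        final_mask = (intercept - lam * self.doses) > L_m + 1e-9
        xf, yf = self.doses[final_mask], self.latencies[final_mask]
        if xf.size > 2 and np.unique(xf).size > 1:
            _, cov = np.polyfit(xf, yf, 1, cov=True)
        else:
            cov = np.full((2, 2), np.nan)
        # the slope is identified only with >= 2 points off the floor
        converged = lam > 0 and int(final_mask.sum()) >= 2
        if not converged:
            warnings.warn("latency slope not identified (non-decreasing in "
                          "dose or all points on the floor); flagging the "
                          "fit as not converged", stacklevel=2)
        return LatencyResults(self, L_0=intercept, lam=lam, L_m=L_m,
                              cov_line=np.asarray(cov, dtype=float),
                              rss=rss, converged=converged,
                              n_regression=int(final_mask.sum()))


@dataclass
class LatencyResults:
    """Fitted dose-latency line with its floor."""

    model: LatencyModel
    L_0: float
    lam: float
    L_m: float
    cov_line: np.ndarray  # covariance of (slope, intercept) from the regression
    rss: float
    converged: bool
    n_regression: int

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(self.cov_line))
        return np.array([se[1], se[0]])  # (L_0, lam) order

    def predict(self, doses) -> np.ndarray:
        return latency_value(self.L_0, self.lam, self.L_m, doses)

    def characteristics(self, C_0: float):
        """(L_M, Delta_L) given the threshold dose from the same neuron's
        Hill fit."""
        return derive_latency_characteristics(self.L_0, self.lam, self.L_m, C_0)

    def summary(self) -> str:
        lines = [
            "Dose-latency line fit",
            "=" * 46,
            f"{'observations':<22}{self.model.doses.size:>12d}",
            f"{'used in regression':<22}{self.n_regression:>12d}",
            f"{'converged':<22}{str(self.converged):>12}",
            f"{'residual SS':<22}{self.rss:>12.4g}",
            "-" * 46,
            f"{'L_0 (ms at C=0)':<22}{self.L_0:>12.4g}",
            f"{'lam (ms/log unit)':<22}{self.lam:>12.4g}",
            f"{'L_m (floor, ms)':<22}{self.L_m:>12.4g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# convenience wrappers
# ---------------------------------------------------------------------------


def fit_hill(doses, rates, F_0: float = 5.0) -> HillResults:
    return HillModel(doses, rates, F_0=F_0).fit()


def fit_latency_line(doses, latencies, floor_tol_ms: float = 5.0) -> LatencyResults:
    return LatencyModel(doses, latencies, floor_tol_ms=floor_tol_ms).fit()


def neuron_curve_values(params: NeuronParamVector, C):
    """(F, L) of a six-parameter neuron at dose(s) C."""
    F = hill_value(params.F_M, params.C_half, params.n, C)
    L = latency_value(params.L_0, params.lam, params.L_m, C)
    return F, L
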