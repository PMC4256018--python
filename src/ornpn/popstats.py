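"""Population-level statistics of fitted dose-response properties.

Per-dose distribution fits (Gaussian firing rates and latencies, lognormal
spontaneous rates), the two-regime heterogeneity line (SD proportional to
the mean below ~100 AP/s, constant above), Pearson correlation matrices of
the 11 curve properties, multinormal estimation of the 6-parameter joint
distribution, and quantile-coupled population curves ("median", "10% most
responsive", ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PARAM_FIELDS, NeuronParamVector, PopulationModel, forward_transform

__all__ = [
    "DistributionFit",
    "HeterogeneityLine",
    "fit_distribution",
    "heterogeneity_regression",
    "correlation_matrix",
    "estimate_multinormal",
    "quantile_curves",
    "nearest_psd",
]

#: properties whose population marginals are lognormal and are therefore
#: log-transformed before correlation analysis
LOGNORMAL_PROPERTIES = ("n", "lam", "L_M")


@dataclass(frozen=True)
class DistributionFit:
    """Maximum-likelihood normal or lognormal fit with KS goodness of fit."""

    family: str  # "normal" | "lognormal"
    mu: float
    sigma: float  # natural-log scale for lognormal
    ks_stat: float
    ks_p: float
    n_obs: int
    degenerate: bool = False

    def median(self) -> float:
        return float(np.exp(self.mu)) if self.family == "lognormal" else self.mu

    def mean(self) -> float:
        if self.family == "lognormal":
            return float(np.exp(self.mu + self.sigma**2 / 2.0))
        return self.mu


@dataclass(frozen=True)
class HeterogeneityLine:
    """Two-regime relation of per-dose SD to per-dose mean: proportional
    (slope = CV) below the breakpoint, constant (plateau) above it."""

    slope: float
    plateau: float
    breakpoint: float
    n_below: int
    n_above: int


def fit_distribution(values, family: str = "normal") -> DistributionFit:
    """ML fit of a normal or lognormal distribution plus a one-sample KS test
    of the data against the fitted CDF."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 5:
        raise ValueError("need at least 5 observations")
    if family == "lognormal":
        if np.any(values <= 0):
            raise ValueError("lognormal fit requires strictly positive values")
        x = np.log(values)
    elif family == "normal":
        x = values
    else:
        raise ValueError(f"unknown family {family!r}")
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))  # MLE
    if sigma == 0.0:
        return DistributionFit(family, mu, 0.0, float("nan"), float("nan"),
                               values.size, degenerate=True)
    ks = stats.kstest(x, "norm", args=(mu, sigma))
    return DistributionFit(family, mu, sigma, float(ks.statistic),
                           float(ks.pvalue), values.size)


def heterogeneity_regression(mu_sigma_pairs, breakpoint: float = 100.0) -> HeterogeneityLine:
    """Fit sigma = slope * mu (zero intercept) below the breakpoint and a
    constant plateau above it."""
    arr = np.asarray(mu_sigma_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (mu, sigma) pairs")
    mu, sig = arr[:, 0], arr[:, 1]
    below = mu < breakpoint
    if below.sum() < 1:
        slope = float("nan")
    else:
        slope = float(np.sum(mu[below] * sig[below]) / np.sum(mu[below] ** 2))
    above = ~below
    plateau = float(sig[above].mean()) if above.any() else float("nan")
    return HeterogeneityLine(slope=slope, plateau=plateau,
                             breakpoint=breakpoint,
                             n_below=int(below.sum()), n_above=int(above.sum()))


def correlation_matrix(table: pd.DataFrame,
                       lognormal_fields=LOGNORMAL_PROPERTIES,
                       bh_correction: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlations of curve properties.

    Lognormally distributed properties are log-transformed first.  Pairs are
    formed with pairwise deletion of missing values; the returned frame has
    one row per unordered pair with columns r, p and n.  ``bh_correction``
    adds Benjamini-Hochberg adjusted p-values (the primary analysis reports
    raw p-values).
    """
    cols = list(table.columns)
    if len(cols) < 2 or len(table) < 5:
        raise ValueError("need >= 2 properties and >= 5 neurons")
    work = table.copy()
    for c in cols:
        if c in lognormal_fields:
            vals = work[c].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError(f"cannot log-transform non-positive {c}")
            work[c] = np.log(vals)
    rows = []
    for a, b in combinations(cols, 2):
        sub = work[[a, b]].dropna()
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append((a, b, float("nan"), float("nan"), len(sub)))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((a, b, float(r), float(p), len(sub)))
    out = pd.DataFrame(rows, columns=["prop_a", "prop_b", "r", "p", "n"])
    if bh_correction:
        p = out["p"].to_numpy()
        order = np.argsort(p)
        m = np.isfinite(p).sum()
        adj = np.full_like(p, np.nan)
        prev = 1.0
        for rank, idx in list(enumerate(order, start=1))[::-1]:
            if not np.isfinite(p[idx]):
                continue
            prev = min(prev, p[idx] * m / rank)
            adj[idx] = prev
        out["p_bh"] = adj
    return out


def nearest_psd(Sigma: np.ndarray) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix onto the PSD cone by clipping negative
    eigenvalues; returns (matrix, was_projected)."""
    Sigma = 0.5 * (Sigma + Sigma.T)
    w, V = np.linalg.eigh(Sigma)
    if w.min() >= 0:
        return Sigma, False
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T, True


def estimate_multinormal(param_table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean vector M and covariance Sigma of the six parameters,
    with n and lam log-transformed (internal scale of PopulationModel)."""
    missing = [c for c in PARAM_FIELDS if c not in param_table.columns]
    if missing:
        raise ValueError(f"parameter table is missing columns {missing}")
    data = param_table[list(PARAM_FIELDS)].dropna()
    if len(data) < 7:
        raise ValueError("need at least 7 complete 6-parameter vectors")
    X = forward_transform(data.to_numpy(dtype=float))
    M = X.mean(axis=0)
    Sigma = np.cov(X, rowvar=False, ddof=1)
    Sigma, projected = nearest_psd(Sigma)
    if projected:  # pragma: no cover - needs a rank-deficient fixture
        import warnings

        warnings.warn("estimated covariance projected to nearest PSD",
                      stacklevel=2)
    return M, Sigma


def estimate_population_model(param_table: pd.DataFrame,
                              template: PopulationModel | None = None,
                              **kwargs) -> PopulationModel:
    """Convenience: wrap estimate_multinormal into a PopulationModel."""
    M, Sigma = estimate_multinormal(param_table)
    base = template.to_dict() if template is not None else {}
    base.update(kwargs)
    base.pop("param_order", None)
    base.pop("log_scale_params", None)
    base["M"], base["Sigma"] = M, Sigma
    return PopulationModel.from_dict(base)


# quantile couplings: which marginal quantile of each parameter builds the
# named population curve (the favourable extreme couples 90% F_M with 10%
# C_half and n; "fastest" couples 10% latencies with a 90% slope)
_RATE_COUPLINGS = {
    "median": {"F_M": 0.5, "C_half": 0.5, "n": 0.5},
    "top10": {"F_M": 0.9, "C_half": 0.1, "n": 0.1},
    "bottom10": {"F_M": 0.1, "C_half": 0.9, "n": 0.9},
}
_LATENCY_COUPLINGS = {
    "median": {"L_0": 0.5, "lam": 0.5, "L_m": 0.5},
    "top10": {"L_0": 0.1, "lam": 0.9, "L_m": 0.1},     # fastest
    "bottom10": {"L_0": 0.9, "lam": 0.1, "L_m": 0.9},  # slowest
}


def quantile_curves(fit_table: pd.DataFrame, which=("median", "top10", "bottom10")
                    ) -> dict[str, NeuronParamVector]:
    """Parameter sets for reconstructed population curves.

    ``fit_table`` holds one row per neuron with the six parameter columns.
    Each named curve couples per-parameter marginal quantiles; e.g. the
    "10% most responsive" curve pairs the 90% quantile of F_M with the 10%
    quantiles of C_half and n.
    """
    if len(fit_table) < 10:
        raise ValueError("need at least 10 fitted neurons")
    out: dict[str, NeuronParamVector] = {}
    for label in which:
        vals = {}
        for p, q in {**_RATE_COUPLINGS[label], **_LATENCY_COUPLINGS[label]}.items():
            vals[p] = float(np.nanquantile(fit_table[p].to_numpy(dtype=float), q))
        out[label] = NeuronParamVector(**vals)
    return out
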