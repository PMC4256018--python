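"""Decomposition of response variability.

Observed variability splits along two axes: its *source* (stimulus vs
biological) and its *level* (irregularity within one unit vs heterogeneity
across units).  With independent components,

    sigma_Ti^2 = sigma_Si^2 + sigma_Bi^2          (within-unit, total =
                                                   stimulus + biological)
    sigma_Th^2 = sigma_Sh^2 + sigma_Bi^2 + sigma_Bh^2
                                                  (across-unit total)

so the unknown biological components follow by subtraction.  The raw
within/across estimates come from a series x repetitions design (repeated
puffs from one cartridge within a series; different identically prepared
cartridges across series) via the one-way random-effects ANOVA estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "decompose_irregularity",
    "decompose_heterogeneity",
    "estimate_within_across",
    "estimate_components_from_series",
    "cv_decomposition",
]


@dataclass
class VarianceComponents:
    """The six variances of the two-level decomposition (measured unit squared).

    ``clipped`` records which biological components were negative before
    clipping to zero (sampling noise can push the subtractions below zero).
    """

    sigma2_Ti: float
    sigma2_Si: float
    sigma2_Bi: float
    sigma2_Th: float
    sigma2_Sh: float
    sigma2_Bh: float
    clipped: list = field(default_factory=list)

    def biological_fraction_irregularity(self) -> float:
        return self.sigma2_Bi / self.sigma2_Ti if self.sigma2_Ti > 0 else float("nan")

    def heterogeneity_share_of_total(self) -> float:
        return self.sigma2_Bh / self.sigma2_Th if self.sigma2_Th > 0 else float("nan")

    def heterogeneity_share_of_biological(self) -> float:
        denom = self.sigma2_Bi + self.sigma2_Bh
        return self.sigma2_Bh / denom if denom > 0 else float("nan")


def _clip(value: float, name: str, clipped: list) -> float:
    if value < 0:
        clipped.append(name)
        warnings.warn(f"negative variance component {name} = {value:.4g} "
                      "clipped to 0", stacklevel=3)
        return 0.0
    return value


def decompose_irregularity(sigma2_Ti: float, sigma2_Si: float,
                           clipped: list | None = None) -> float:
    """Biological irregularity: total within-unit variance minus the
    stimulus contribution, clipped at zero."""
    if sigma2_Ti < 0 or sigma2_Si < 0:
        raise ValueError("variances must be >= 0")
    clipped = clipped if clipped is not None else []
    return _clip(sigma2_Ti - sigma2_Si, "sigma2_Bi", clipped)


def decompose_heterogeneity(sigma2_Th: float, sigma2_Sh: float,
                            sigma2_Bi: float,
                            clipped: list | None = None) -> float:
    """Biological heterogeneity: across-unit variance minus stimulus
    heterogeneity and within-unit biological irregularity, clipped at zero."""
    if min(sigma2_Th, sigma2_Sh, sigma2_Bi) < 0:
        raise ValueError("variances must be >= 0")
    clipped = clipped if clipped is not None else []
    return _clip(sigma2_Th - sigma2_Sh - sigma2_Bi, "sigma2_Bh", clipped)


def estimate_within_across(values, series) -> dict:
    """Raw within-series (irregularity) and across-series (heterogeneity)
    variance estimates from a series x repetitions layout.

    Within = pooled within-series variance.  Across = variance of the series
    means minus within/n0 (one-way random-effects ANOVA estimator, with n0
    the effective repetitions per series under unbalance).  Also returns the
    estimates as CVs relative to the grand mean.
    """
    values = np.asarray(values, dtype=float)
    series = np.asarray(series)
    if values.shape != series.shape:
        raise ValueError("values and series labels must align")
    groups = pd.Series(values).groupby(pd.Series(series))
    sizes = groups.size().to_numpy(dtype=float)
    if sizes.size < 2:
        raise ValueError("need at least 2 series to estimate heterogeneity")
    if (sizes < 2).any():
        raise ValueError("each series needs at least 2 repetitions")
    means = groups.mean().to_numpy()
    variances = groups.var(ddof=1).to_numpy()
    N = sizes.sum()
    k = sizes.size
    within = float(np.sum((sizes - 1) * variances) / np.sum(sizes - 1))
    grand = float(np.sum(sizes * means) / N)
    # between-series mean square, weighted for unbalanced designs
    msb = float(np.sum(sizes * (means - grand) ** 2) / (k - 1))
    n0 = float((N - np.sum(sizes**2) / N) / (k - 1))
    between = max((msb - within) / n0, 0.0)
    return {
        "within_var": within,
        "between_var": between,
        "grand_mean": grand,
        "within_cv": np.sqrt(within) / abs(grand) if grand else float("nan"),
        "between_cv": np.sqrt(between) / abs(grand) if grand else float("nan"),
        "n_series": int(k),
        "n_total": int(N),
    }


def estimate_components_from_series(
    values, series,
    stimulus_within_var: float = 0.0,
    stimulus_between_var: float = 0.0,
) -> VarianceComponents:
    """Estimate the full decomposition from a series design.

    The pooled within-series variance is the total irregularity.  The total
    heterogeneity (the variance of single measurements taken across
    different units) is the ANOVA between-series variance *plus* the
    within-series variance, because a measurement on a new unit carries that
    unit's irregularity once.  The independently measured stimulus
    components are then subtracted to isolate the biological parts.
    """
    raw = estimate_within_across(values, series)
    clipped: list = []
    sigma2_Ti = raw["within_var"]
    sigma2_Th = raw["between_var"] + raw["within_var"]
    sigma2_Bi = decompose_irregularity(sigma2_Ti, stimulus_within_var, clipped)
    sigma2_Bh = decompose_heterogeneity(sigma2_Th, stimulus_between_var,
                                        sigma2_Bi, clipped)
    return VarianceComponents(
        sigma2_Ti=sigma2_Ti, sigma2_Si=stimulus_within_var,
        sigma2_Bi=sigma2_Bi, sigma2_Th=sigma2_Th,
        sigma2_Sh=stimulus_between_var, sigma2_Bh=sigma2_Bh, clipped=clipped)


def cv_decomposition(cv_Ti: float, cv_Sh: float, cv_Si: float,
                     cv_Th: float) -> dict:
    """Combine published coefficients of variation on the CV^2 scale.

    When only CVs are available the components are treated as variances at a
    common mean (flagged: this is an approximation).  Returns the biological
    CVs and the fractional shares.
    """
    comps: list = []
    cv2_Bi = decompose_irregularity(cv_Ti**2, cv_Si**2, comps)
    cv2_Bh = decompose_heterogeneity(cv_Th**2, cv_Sh**2, cv2_Bi, comps)
    return {
        "cv_Bi": float(np.sqrt(cv2_Bi)),
        "cv_Bh": float(np.sqrt(cv2_Bh)),
        "irregularity_biological_fraction": cv2_Bi / cv_Ti**2 if cv_Ti else float("nan"),
        "heterogeneity_share_of_total": cv2_Bh / cv_Th**2 if cv_Th else float("nan"),
        "heterogeneity_share_of_biological": (
            cv2_Bh / (cv2_Bi + cv2_Bh) if (cv2_Bi + cv2_Bh) > 0 else float("nan")),
        "approximation": "common-mean CV^2 scale",
        "clipped": comps,
    }
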