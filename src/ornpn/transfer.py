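"""ORN-to-PN transfer functions.

At any dose both populations respond; eliminating the dose between the two
fitted curves maps the ORN response directly onto the PN response.  For
firing rate, solving the ORN Hill curve for C and substituting into the PN
curve gives

    F_P = F_PM / (1 + K * (F_RM / F_R - 1)^(n_P / n_R)),
    K   = 10^{n_P (C_P1/2 - C_R1/2)}

- the same form as a Hill function except for the "-1" term in the
denominator.  For latency, eliminating C between the two lines gives the
affine map

    L_P = max(L_P0 - (lam_P / lam_R) (L_R0 - L_R), L_Pm)

with slope lam_P/lam_R and intercept L_P0 - (lam_P/lam_R) L_R0.  The
absolute positions of the curves on the dose axis (C_R1/2, C_P1/2 enter only
through their difference) are lost in the transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doseresponse import hill_value, latency_value

__all__ = [
    "rate_transfer_constant",
    "firing_transfer",
    "f_half_input",
    "latency_transfer",
    "latency_transfer_line",
    "numeric_transfer",
    "sensitivity_shift",
    "TransferCurve",
]


def rate_transfer_constant(n_P: float, C_P_half: float, C_R_half: float) -> float:
    """The constant K = 10^{n_P (C_P1/2 - C_R1/2)} of the rate transfer."""
    return float(10.0 ** (n_P * (C_P_half - C_R_half)))


def firing_transfer(orn, pn, F_R):
    """PN firing rate as a function of the ORN firing rate at the same dose.

    ``orn`` = (F_RM, C_R1/2, n_R) and ``pn`` = (F_PM, C_P1/2, n_P).  Valid
    for 0 < F_R < F_RM (the open dynamic range of the ORN curve).
    """
    F_RM, C_R_half, n_R = orn
    F_PM, C_P_half, n_P = pn
    F_R = np.asarray(F_R, dtype=float)
    if np.any((F_R <= 0) | (F_R >= F_RM)):
        raise ValueError("F_R must lie strictly inside (0, F_RM)")
    K = rate_transfer_constant(n_P, C_P_half, C_R_half)
    out = F_PM / (1.0 + K * (F_RM / F_R - 1.0) ** (n_P / n_R))
    return out if out.ndim else float(out)


def f_half_input(orn, pn) -> float:
    """ORN input rate driving the PN to half its maximum:
    F_R = F_RM / (1 + K^{-n_R/n_P})."""
    F_RM, C_R_half, n_R = orn
    _, C_P_half, n_P = pn
    K = rate_transfer_constant(n_P, C_P_half, C_R_half)
    return float(F_RM / (1.0 + K ** (-n_R / n_P)))


def latency_transfer(orn, pn, L_R):
    """PN latency as a function of the ORN latency at the same dose.

    ``orn`` = (L_R0, lam_R) and ``pn`` = (L_P0, lam_P, L_Pm).  The map is
    affine with slope lam_P/lam_R, floored at the PN minimum latency."""
    L_R0, lam_R = orn
    L_P0, lam_P, L_Pm = pn
    if lam_R <= 0:
        raise ValueError("lam_R must be > 0 (vertical mapping otherwise)")
    L_R = np.asarray(L_R, dtype=float)
    out = np.maximum(L_P0 - (lam_P / lam_R) * (L_R0 - L_R), L_Pm)
    return out if out.ndim else float(out)


def latency_transfer_line(orn, pn) -> tuple[float, float]:
    """(slope, intercept) of the unfloored latency transfer line."""
    L_R0, lam_R = orn
    L_P0, lam_P, _ = pn
    slope = lam_P / lam_R
    return float(slope), float(L_P0 - slope * L_R0)


def numeric_transfer(orn_params, pn_params, dose_grid, kind: str = "rate"):
    """Sampled transfer curve by explicit dose elimination.

    For each dose on the grid the ORN and PN responses are evaluated from
    their fitted curves and paired; this is the independent oracle for the
    closed-form transfer expressions.  Returns (input, output) arrays.
    """
    C = np.asarray(dose_grid, dtype=float)
    if kind == "rate":
        F_RM, C_R_half, n_R = orn_params
        F_PM, C_P_half, n_P = pn_params
        x = hill_value(F_RM, C_R_half, n_R, C)
        y = hill_value(F_PM, C_P_half, n_P, C)
    elif kind == "latency":
        L_R0, lam_R = orn_params[:2]
        L_P0, lam_P, L_Pm = pn_params
        x = L_R0 - lam_R * C  # unfloored ORN regime
        y = latency_value(L_P0, lam_P, L_Pm, C)
    else:
        raise ValueError(f"unknown transfer kind {kind!r}")
    return x, y


def sensitivity_shift(orn_C_half: float, pn_C_half: float) -> float:
    """Fold change in sensitivity implied by the ED50 separation:
    10^(C_R1/2 - C_P1/2)."""
    return float(10.0 ** (orn_C_half - pn_C_half))


@dataclass(frozen=True)
class TransferCurve:
    """A sampled ORN-to-PN transfer curve with its summary constants."""

    kind: str  # "rate" | "latency"
    inputs: np.ndarray
    outputs: np.ndarray
    K: float | None = None
    F_half_input: float | None = None
    slope: float | None = None
    intercept: float | None = None
    quantile_label: str = "median"

    @classmethod
    def from_params(cls, orn, pn, kind: str = "rate", n_points: int = 200,
                    quantile_label: str = "median") -> "TransferCurve":
        """Build the curve over the ORN input range [F_0-ish, 0.99 F_RM]
        (rate) or the unfloored latency range (latency)."""
        if kind == "rate":
            F_RM = orn[0]
            x = np.linspace(0.01 * F_RM, 0.99 * F_RM, n_points)
            y = firing_transfer(orn, pn, x)
            return cls(kind, x, np.asarray(y),
                       K=rate_transfer_constant(pn[2], pn[1], orn[1]),
                       F_half_input=f_half_input(orn, pn),
                       quantile_label=quantile_label)
        if kind == "latency":
            L_R0, lam_R = orn[:2]
            L_Rm = orn[2] if len(orn) > 2 else 0.0
            x = np.linspace(max(L_Rm, 1.0), L_R0 + 3.0 * lam_R, n_points)
            y = latency_transfer((L_R0, lam_R), pn, x)
            slope, intercept = latency_transfer_line((L_R0, lam_R), pn)
            return cls(kind, x, np.asarray(y), slope=slope,
                       intercept=intercept, quantile_label=quantile_label)
        raise ValueError(f"unknown transfer kind {kind!r}")

    def plot(self, ax=None, **kwargs):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.inputs, self.outputs, **kwargs)
        unit = "AP/s" if self.kind == "rate" else "ms"
        ax.set_xlabel(f"ORN response ({unit})")
        ax.set_ylabel(f"PN response ({unit})")
        return ax
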