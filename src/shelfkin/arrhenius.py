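"""Arrhenius temperature modelling of kinetic rate constants.

The temperature dependence of a degradation rate constant is described by

    ln k = ln A0 - Ea / (R T)

with A0 the pre-exponential (frequency) factor, Ea the activation energy
(J mol^-1 internally, reported in kJ mol^-1), R = 8.314 J mol^-1 K^-1 and T
the absolute temperature.  Fitting is ordinary least squares of ln k on 1/T;
an inverse-variance weighted variant is available when per-point standard
errors are supplied.

Alongside (Ea, ln A0) the fit reports k_ref, the rate constant evaluated at
a fixed reference temperature T_ref (default 277.45 K, i.e. ~4 °C), which is
the conventional way refrigerated-storage studies tabulate the temperature
model.  k_ref is derived from the fitted curve, so re-referencing changes
k_ref but never Ea or the predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError

R_GAS = 8.314          # J mol^-1 K^-1
T_REF_DEFAULT = 277.45  # K
CELSIUS_OFFSET = 273.15

__all__ = [
    "R_GAS",
    "T_REF_DEFAULT",
    "RatePoint",
    "ArrheniusFit",
    "celsius_to_kelvin",
    "fit_arrhenius",
    "predict_k",
    "compare_ea",
]


def celsius_to_kelvin(temp_C: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(temp_C, dtype=float) + CELSIUS_OFFSET


@dataclass(frozen=True)
class RatePoint:
    """A rate constant observed at one absolute temperature."""

    temperature_K: float
    k: float                   # day^-1
    k_se: float | None = None  # optional weighting source

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise DomainError("temperature must be positive (Kelvin)")
        if self.k <= 0:
            raise DomainError("rate constant must be positive")


@dataclass
class ArrheniusFit:
    """Fitted Arrhenius temperature model for one attribute × treatment."""

    Ea: float                  # activation energy, kJ mol^-1
    Ea_se: float               # kJ mol^-1
    ln_pre_exponential: float  # ln A0, dimensionless
    k_ref: float               # day^-1, fitted curve at T_ref
    T_ref: float               # K
    r2: float
    n_points: int

    def to_record(self) -> dict:
        return {
            "k_ref": self.k_ref,
            "Ea_kJ_mol": self.Ea,
            "Ea_se": self.Ea_se,
            "R2": self.r2,
        }


def fit_arrhenius(
    points: Sequence[RatePoint],
    t_ref: float = T_REF_DEFAULT,
    weighted: bool = False,
) -> ArrheniusFit:
    """Fit ln k = ln A0 - Ea/(R T) across >= 3 temperatures.

    Parameters
    ----------
    points
        Rate constants with absolute temperatures; all k must be positive.
    t_ref
        Reference temperature (K) at which ``k_ref`` is evaluated.
    weighted
        If True, weight each point by 1/se(ln k)^2 with
        se(ln k) = k_se / k (delta method); requires k_se on every point.
    """
    if len(points) < 2:
        raise InsufficientDataError("Arrhenius fit requires >= 2 rate points")
    temps = np.array([p.temperature_K for p in points], dtype=float)
    ks = np.array([p.k for p in points], dtype=float)
    n_distinct = len(np.unique(temps))
    if n_distinct < 2:
        raise InsufficientDataError("need >= 2 distinct temperatures")
    if n_distinct == 2:
        # exact two-point line: slope has no residual df, R^2 is undefined
        warnings.warn(
            "only 2 distinct temperatures: exact fit, R^2 undefined",
            stacklevel=2,
        )
        t2 = np.array(sorted(set(temps)))
        x2 = 1.0 / t2
        y2 = np.array([np.log(ks[temps == ti].mean()) for ti in t2])
        slope = (y2[1] - y2[0]) / (x2[1] - x2[0])
        intercept = y2[0] - slope * x2[0]
        ea_J = -slope * R_GAS
        return ArrheniusFit(
            Ea=ea_J / 1000.0,
            Ea_se=float("nan"),
            ln_pre_exponential=float(intercept),
            k_ref=math.exp(intercept - ea_J / (R_GAS * t_ref)),
            T_ref=t_ref,
            r2=float("nan"),
            n_points=len(points),
        )
    x = 1.0 / temps
    y = np.log(ks)
    if weighted:
        ses = np.array(
            [p.k_se if p.k_se is not None else np.nan for p in points], dtype=float
        )
        if np.isnan(ses).any() or (ses <= 0).any():
            raise DomainError("weighted fit requires positive k_se on every point")
        w = (ks / ses) ** 2
        slope, intercept, slope_se, r2 = _wls_line(x, y, w)
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        slope_se, r2 = float(res.stderr), float(res.rvalue**2)
        if np.allclose(y, y[0]):
            # temperature-independent rates: define R^2 = 1 for the flat fit
            slope, slope_se, r2 = 0.0, 0.0, 1.0
            intercept = float(y[0])
    ea_J = -slope * R_GAS
    return ArrheniusFit(
        Ea=ea_J / 1000.0,
        Ea_se=slope_se * R_GAS / 1000.0,
        ln_pre_exponential=intercept,
        k_ref=math.exp(intercept - ea_J / (R_GAS * t_ref)),
        T_ref=t_ref,
        r2=r2,
        n_points=len(points),
    )


def _wls_line(x, y, w):
    """Weighted least squares line; returns slope, intercept, slope SE, R^2."""
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    dof = len(x) - 2
    s2 = np.sum(w * resid**2) / dof if dof > 0 else 0.0
    slope_se = math.sqrt(s2 / sxx)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(slope_se), float(r2)


def predict_k(fit: ArrheniusFit, temperature_K: float) -> float:
    """Evaluate the fitted Arrhenius curve at an absolute temperature."""
    if temperature_K <= 0:
        raise DomainError("temperature must be positive (Kelvin)")
    return math.exp(
        fit.ln_pre_exponential - fit.Ea * 1000.0 / (R_GAS * temperature_K)
    )


def compare_ea(
    fitA: ArrheniusFit,
    fitB: ArrheniusFit,
    nA: int | None = None,
    nB: int | None = None,
) -> tuple[float, float]:
    """Two-sided test of equal activation energies between two fits.

    The statistic is (EaA - EaB) / sqrt(seA^2 + seB^2).  When replicate-level
    sample sizes ``nA``/``nB`` are given the reference distribution is a
    Welch t with Satterthwaite degrees of freedom; otherwise a standard
    normal is used (large-sample / known-SE convention).

    Returns
    -------
    (statistic, p_value)
    """
    seA, seB = fitA.Ea_se, fitB.Ea_se
    if not (seA > 0 or seB > 0):
        raise DomainError(
            "both fits have zero/missing Ea standard errors; "
            "fit per replicate to obtain uncertainties"
        )
    denom = math.sqrt(seA**2 + seB**2)
    if denom == 0:
        return 0.0, 1.0
    z = (fitA.Ea - fitB.Ea) / denom
    if nA is not None and nB is not None:
        vA, vB = seA**2, seB**2
        df = (vA + vB) ** 2 / (vA**2 / (nA - 1) + vB**2 / (nB - 1))
        p = float(2 * stats.t.sf(abs(z), df))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p
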