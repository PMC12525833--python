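"""Ionic-strength and temperature dependence of formation constants.

Ionic strength follows the one-parameter extended Debye–Hückel form

    log beta(I) = log beta0 - 0.51 z* sqrt(I)/(1 + 1.5 sqrt(I)) + C I

with z* = sum of squared reactant charges minus sum of squared product
charges for the formation reaction as written (protons released by
hydroxo species count on the product side).  C is an empirical
short-range interaction coefficient obtained by least squares.

Temperature follows the integrated van't Hoff equation with constant
enthalpy,

    log beta(T) = log beta_theta + [dH / (R ln 10)] (1/theta - 1/T),

theta = 298.15 K, R = 8.314 J/(K mol), dH in kJ/mol (the R ln10 divisor
restores dimensional consistency).  Gibbs energies derive from
dG = -R T ln10 logbeta and T dS = dH - dG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS", "THETA",
    "IonicStrengthFit", "VantHoffFit", "ThermoTriplet",
    "z_star", "debye_huckel_term", "logbeta_at_ionic_strength",
    "fit_debye_huckel", "logbeta_at_temperature", "fit_vant_hoff",
    "thermo_triplet",
]

R_GAS = 8.314        # J / (K mol)
THETA = 298.15       # K
LN10 = float(np.log(10.0))
_A_DH = 0.51         # Debye-Hueckel slope used by the source constants
_B_DH = 1.5


def z_star(reactant_charges: Sequence[int], product_charges: Sequence[int]) -> int:
    """Charge parameter: sum of squared reactant charges minus products."""
    return int(sum(z * z for z in reactant_charges)
               - sum(z * z for z in product_charges))


def debye_huckel_term(z_star_value: float, ionic_strength) -> np.ndarray | float:
    I = np.asarray(ionic_strength, dtype=float)
    if np.any(I < 0):
        raise ValueError("ionic strength must be non-negative")
    s = np.sqrt(I)
    out = _A_DH * z_star_value * s / (1.0 + _B_DH * s)
    return float(out) if np.isscalar(ionic_strength) else out


def logbeta_at_ionic_strength(logbeta0: float, C: float, z_star_value: float,
                              ionic_strength) -> np.ndarray | float:
    """Evaluate the extended Debye–Hückel expression at I (mol/L)."""
    I = np.asarray(ionic_strength, dtype=float)
    out = logbeta0 - debye_huckel_term(z_star_value, I) + C * I
    return float(out) if np.isscalar(ionic_strength) else out


@dataclass
class IonicStrengthFit:
    logbeta0: float
    C: float
    z_star: float
    logbeta0_se: float
    C_se: float
    logbeta0_ci95: float
    C_ci95: float
    points: list[tuple[float, float]]
    residuals: np.ndarray

    def predict(self, ionic_strength):
        return logbeta_at_ionic_strength(self.logbeta0, self.C, self.z_star,
                                         ionic_strength)


def fit_debye_huckel(points: Sequence[tuple], z_star_value: float,
                     weighted: bool = False) -> IonicStrengthFit:
    """Least-squares (logbeta0, C) from (I, logbeta[, sigma]) points.

    After moving the fixed Debye–Hückel term to the response the model
    is linear, ``y + DH(I) = logbeta0 + C I``; the default is unweighted
    (sigmas, when present in the points, are used only if
    ``weighted=True``).
    """
    if len(points) < 2:
        raise ValueError("at least two (I, logbeta) points are required")
    I = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(I)) < 2:
        raise ValueError("at least two distinct ionic strengths are required")
    sig = np.array([p[2] if len(p) > 2 else 1.0 for p in points], dtype=float)
    w = 1.0 / sig**2 if weighted else np.ones_like(I)

    yy = y + debye_huckel_term(z_star_value, I)
    X = np.column_stack([np.ones_like(I), I])
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], yy * W, rcond=None)
    resid = yy - X @ coef
    dof = len(I) - 2
    if dof > 0:
        s2 = float(np.sum(w * resid**2) / dof)
        cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
        se = np.sqrt(np.diag(cov))
        tcrit = stats.t.ppf(0.975, dof)
    else:
        se = np.zeros(2)
        tcrit = 0.0
    return IonicStrengthFit(
        logbeta0=float(coef[0]), C=float(coef[1]), z_star=float(z_star_value),
        logbeta0_se=float(se[0]), C_se=float(se[1]),
        logbeta0_ci95=float(tcrit * se[0]), C_ci95=float(tcrit * se[1]),
        points=[(float(a), float(b)) for a, b in zip(I, y)],
        residuals=resid,
    )


def logbeta_at_temperature(logbeta_theta: float, deltaH_kJ: float,
                           T_K: float) -> float:
    """van't Hoff extrapolation of log beta from 298.15 K to T (K)."""
    T = np.asarray(T_K, dtype=float)
    if np.any(T < 273.0) or np.any(T > 373.0):
        raise ValueError("temperature outside the 273-373 K validity range")
    slope = deltaH_kJ * 1000.0 / (R_GAS * LN10)
    out = logbeta_theta + slope * (1.0 / THETA - 1.0 / T)
    return float(out) if np.isscalar(T_K) else out


@dataclass
class VantHoffFit:
    logbeta_theta: float
    deltaH_theta: float  # kJ/mol
    logbeta_theta_se: float
    deltaH_se: float
    theta: float
    points: list[tuple[float, float]]
    residuals: np.ndarray

    def predict(self, T_K):
        return logbeta_at_temperature(self.logbeta_theta, self.deltaH_theta, T_K)


def fit_vant_hoff(points: Sequence[tuple[float, float]]) -> VantHoffFit:
    """Least-squares (logbeta_theta, dH_theta) from (T K, logbeta) points."""
    if len(points) < 2:
        raise ValueError("at least two temperatures are required")
    T = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(T)) < 2:
        raise ValueError("at least two distinct temperatures are required")
    x = 1.0 / THETA - 1.0 / T
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(T) - 2
    if dof > 0:
        s2 = float(np.sum(resid**2) / dof)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.zeros(2)
    conv = R_GAS * LN10 / 1000.0  # slope (log units * K) -> kJ/mol
    return VantHoffFit(
        logbeta_theta=float(coef[0]),
        deltaH_theta=float(coef[1] * conv),
        logbeta_theta_se=float(se[0]),
        deltaH_se=float(se[1] * conv),
        theta=THETA,
        points=[(float(a), float(b)) for a, b in zip(T, y)],
        residuals=resid,
    )


@dataclass(frozen=True)
class ThermoTriplet:
    deltaG: float   # kJ/mol
    deltaH: float   # kJ/mol
    TdeltaS: float  # kJ/mol
    T: float        # K


def thermo_triplet(logbeta_25: float, deltaH: float, T: float = THETA) -> ThermoTriplet:
    """dG = -R T ln10 logbeta (kJ/mol); T dS = dH - dG, exactly."""
    dG = -LN10 * R_GAS * T * logbeta_25 / 1000.0
    return ThermoTriplet(deltaG=dG, deltaH=float(deltaH),
                         TdeltaS=float(deltaH) - dG, T=float(T))
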