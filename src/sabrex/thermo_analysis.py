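"""Eyring activation analysis and polarization bookkeeping.

Transition-state theory relates the temperature dependence of the ligand
dissociation rate constant to the activation enthalpy and entropy,

    k_d(T) = (k_B T / h) * exp(dS / R) * exp(-dH / (R T)),

with transmission coefficient 1.  Fitting is done on the linearized form
ln(k_d / T) = ln(k_B / h) + dS/R - dH/(R T) by weighted least squares.
Also provides the inverse-variance weighted mean used to average k_d
estimates from the different exchange analyses, and the thermal-equilibrium
polarization / signal-enhancement conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "EyringResult",
    "RateTable",
    "eyring_rate",
    "fit_eyring",
    "weighted_mean_kd",
    "thermal_polarization",
    "enhancement",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 values (SI units)."""

    k_B: float = 1.380649e-23          # J/K
    h: float = 6.62607015e-34          # J s
    hbar: float = 1.054571817e-34      # J s
    R_gas: float = 8.314462618         # J/(mol K)
    gamma_1H: float = 2.6752218744e8   # rad/(s T)
    gamma_15N: float = -2.7126e7       # rad/(s T), negative gyromagnetic ratio
    B0: float = 9.4                    # T, spectrometer field


CONSTANTS = PhysicalConstants()


@dataclass
class RateTable:
    """(T, k_d, sigma) rows, optionally labeled by the analysis model."""

    temperature: np.ndarray
    k_d: np.ndarray
    sigma: np.ndarray | None = None
    model: Sequence[str] | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.k_d = np.asarray(self.k_d, dtype=float)
        if self.temperature.ndim != 1:
            raise ValueError("temperature must be one-dimensional")
        if len(np.unique(self.temperature)) != self.temperature.size:
            raise ValueError("temperatures must be distinct")
        if np.any(self.temperature <= 0):
            raise ValueError("temperatures must be positive (K)")
        if self.k_d.shape != self.temperature.shape or np.any(self.k_d <= 0):
            raise ValueError("k_d must be positive, one per temperature")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.k_d.shape or np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive, one per row")

    def __len__(self) -> int:
        return self.temperature.size


@dataclass
class EyringResult:
    """Activation enthalpy and entropy with their covariance."""

    dH: float          # kJ/mol
    dS: float          # J/(mol K)
    sigma_dH: float    # kJ/mol
    sigma_dS: float    # J/(mol K)
    covar: np.ndarray  # 2x2, (dH kJ/mol, dS J/mol/K)
    kappa: float = 1.0


def eyring_rate(dH: float, dS: float, T: "float | np.ndarray",
                kappa: float = 1.0) -> "float | np.ndarray":
    """Eyring rate constant (s^-1).

    ``dH`` in kJ/mol, ``dS`` in J/(mol K), ``T`` in K.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    c = CONSTANTS
    out = (kappa * c.k_B * T / c.h
           * np.exp(dS / c.R_gas)
           * np.exp(-1e3 * dH / (c.R_gas * T)))
    return float(out) if out.ndim == 0 else out


def fit_eyring(table: RateTable) -> EyringResult:
    """Weighted linear Eyring regression of ln(k_d / T) on 1/T.

    With y = ln(k_d/T): slope = -dH/R_gas and intercept = ln(k_B/h) + dS/R_gas.
    Measurement errors propagate onto the log scale as sigma_y = sigma/k_d,
    so the weights are (k_d/sigma)^2; the parameter covariance is the
    known-variance expression (X' W X)^-1 (unit weights and a residual-scaled
    covariance are used when no uncertainties are given).
    """
    if len(table) < 3:
        raise ValueError("Eyring fit needs at least 3 temperatures")
    T = table.temperature
    if np.ptp(T) == 0:
        raise ValueError("temperatures have zero spread")
    x = 1.0 / T
    y = np.log(table.k_d / T)
    X = np.column_stack([x, np.ones_like(x)])
    if table.sigma is not None:
        w = (table.k_d / table.sigma) ** 2
        scale_cov = False
    else:
        w = np.ones_like(y)
        scale_cov = True
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    cov = np.linalg.inv(XtWX)
    if scale_cov:
        resid = y - X @ beta
        dof = max(len(y) - 2, 1)
        cov = cov * float(resid @ resid) / dof
    c = CONSTANTS
    slope, intercept = beta
    dH = -slope * c.R_gas / 1e3                       # kJ/mol
    dS = (intercept - math.log(c.k_B / c.h)) * c.R_gas
    jac = np.array([[-c.R_gas / 1e3, 0.0], [0.0, c.R_gas]])
    cov_out = jac @ cov @ jac.T
    return EyringResult(dH=float(dH), dS=float(dS),
                        sigma_dH=float(np.sqrt(cov_out[0, 0])),
                        sigma_dS=float(np.sqrt(cov_out[1, 1])),
                        covar=cov_out)


def weighted_mean_kd(values: Sequence[float], sigmas: Sequence[float]
                     ) -> tuple[float, float]:
    """Inverse-variance weighted mean of rate constants.

    mean = sum(k_i / s_i^2) / sum(1 / s_i^2);  sigma = (sum 1/s_i^2)^(-1/2).
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if v.shape != s.shape or v.ndim != 1 or v.size == 0:
        raise ValueError("values and sigmas must be equal-length 1-d arrays")
    if np.any(s <= 0):
        if v.size == 1:
            return float(v[0]), float(s[0])
        raise ValueError("all sigmas must be positive")
    w = 1.0 / s ** 2
    return float(np.sum(w * v) / np.sum(w)), float(np.sum(w) ** -0.5)


def thermal_polarization(gamma: float, B0: float, T: float) -> float:
    """Thermal-equilibrium spin-1/2 polarization.

    P_th = tanh(hbar |gamma| B0 / (2 k_B T)); the magnitude of the
    gyromagnetic ratio is used (the sign only orients the polarization).
    """
    if B0 <= 0 or T <= 0:
        raise ValueError("B0 and T must be positive")
    c = CONSTANTS
    return math.tanh(c.hbar * abs(gamma) * B0 / (2.0 * c.k_B * T))


def enhancement(P: float, P_th: float) -> float:
    """Signal enhancement factor epsilon = P / P_th."""
    return P / P_th
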