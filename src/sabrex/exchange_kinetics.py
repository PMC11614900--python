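"""Hyperpolarized 15N ligand-exchange kinetics.

After a spin-order-transfer block, the 15N magnetization of the equatorially
bound substrate (M_e) exchanges with the free-substrate pool (M_f) during
the mixing interval tau_e while both relax.  Two complementary analyses
extract the complex dissociation rate constant k_d:

* *eigenvalue analysis*: a global biexponential fit
  M(t) = A exp(-R t) + B exp(-k t) + C with the decay constants R (slow,
  effective relaxation) and k (fast, effective exchange) shared between the
  bound and free curves; k relates to k_d through
  ``k_d = k / (0.5 + [CsS2]/[S])``.
* *mechanistic models*: first-order magnetization balance for the two-site
  exchange ``CsS2 <-> S2`` (two pools) or ``CsS2 <-> CsS + S`` (three
  pools, with an intermediate mono-substrate complex), solved by matrix
  exponential and fitted directly.

Rate convention: the complex loses *a* ligand at total rate k_d (complex
lifetime 1/k_d); since the two equatorial ligands dissociate at the same
rate, a chosen single ligand leaves at k_d/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ExchangeSystem",
    "KineticsDataset",
    "BiexpFitResult",
    "ModelFitResult",
    "DegenerateRatesWarning",
    "biexp_eval",
    "fit_biexp_global",
    "kd_from_eigenvalue",
    "rate_matrix",
    "simulate_model",
    "fit_model",
]

MODELS = ("eigen", "simplified", "full")


class DegenerateRatesWarning(UserWarning):
    """The two fitted decay constants collapsed onto each other."""


# ---------------------------------------------------------------------------
# containers

@dataclass
class ExchangeSystem:
    """Physical parameters of the bound/free substrate exchange.

    Parameters
    ----------
    k_d:
        Dissociation rate constant (s^-1); complex lifetime is 1/k_d and a
        single chosen ligand dissociates at k_d/2.
    c_complex, c_free:
        Concentrations of the bis-substrate complex [CsS2] and of the free
        substrate [S] (same unit, typically mM); only their ratio matters.
    R_e, R_f:
        Longitudinal 15N relaxation rates (s^-1) of bound / free substrate.
    k_assoc:
        Pseudo-first-order re-association rate (s^-1) of the three-pool
        model; ``None`` selects the fast-re-association default 20 * k_d.
    """

    k_d: float
    c_complex: float
    c_free: float
    R_e: float = 0.0
    R_f: float = 0.0
    k_assoc: float | None = None

    def __post_init__(self):
        if self.k_d < 0 or self.R_e < 0 or self.R_f < 0:
            raise ValueError("rates must be non-negative")
        if self.c_complex <= 0 or self.c_free <= 0:
            raise ValueError("concentrations must be positive")
        if self.k_assoc is not None and self.k_assoc <= 0:
            raise ValueError("k_assoc must be positive")

    @property
    def ratio(self) -> float:
        """Bound-to-free concentration ratio r = [CsS2]/[S]."""
        return self.c_complex / self.c_free

    @property
    def k_assoc_eff(self) -> float:
        return 20.0 * self.k_d if self.k_assoc is None else self.k_assoc


@dataclass
class KineticsDataset:
    """Mixing-time series of bound (M_e) and free (M_f) 15N amplitudes."""

    tau_e: np.ndarray
    M_e: np.ndarray
    M_f: np.ndarray
    sigma_e: np.ndarray | None = None
    sigma_f: np.ndarray | None = None
    temperature: float | None = None   # K
    ratio: float | None = None         # [CsS2]/[S]

    def __post_init__(self):
        self.tau_e = np.asarray(self.tau_e, dtype=float)
        self.M_e = np.asarray(self.M_e, dtype=float)
        self.M_f = np.asarray(self.M_f, dtype=float)
        if self.tau_e.ndim != 1:
            raise ValueError("tau_e must be one-dimensional")
        if np.any(self.tau_e < 0):
            raise ValueError("mixing times must be non-negative")
        if np.any(np.diff(self.tau_e) <= 0):
            raise ValueError("non-monotone mixing times")
        for name in ("M_e", "M_f"):
            arr = getattr(self, name)
            if arr.shape != self.tau_e.shape:
                raise ValueError(f"{name} must match tau_e in length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite amplitudes")
        for name in ("sigma_e", "sigma_f"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != self.tau_e.shape or np.any(val <= 0):
                    raise ValueError(f"{name} must be positive, same length")
                setattr(self, name, val)

    def __len__(self) -> int:
        return self.tau_e.size

    def normalized(self) -> tuple["KineticsDataset", float]:
        """Jointly scale both curves so max(M_e) = 1; returns (data, scale)."""
        scale = float(np.max(np.abs(self.M_e)))
        if scale == 0:
            raise ValueError("cannot normalize all-zero bound curve")
        return KineticsDataset(
            self.tau_e, self.M_e / scale, self.M_f / scale,
            None if self.sigma_e is None else self.sigma_e / scale,
            None if self.sigma_f is None else self.sigma_f / scale,
            self.temperature, self.ratio), scale


@dataclass
class BiexpFitResult:
    """Shared-eigenvalue biexponential fit of the bound and free curves."""

    R: float
    k: float
    sigma_R: float
    sigma_k: float
    amplitudes: dict            # A_e, B_e, C_e, A_f, B_f, C_f
    covar: np.ndarray | None
    redchi: float
    degenerate: bool = False

    @property
    def eigenvalue_gap(self) -> float:
        return self.k - self.R


@dataclass
class ModelFitResult:
    """Direct fit of a mechanistic exchange model."""

    model_id: str
    k_d: float
    sigma_kd: float
    R: float
    sigma_R: float
    P_e0: float
    redchi: float
    covar: np.ndarray | None
    residuals: np.ndarray


# ---------------------------------------------------------------------------
# eigenvalue analysis

def biexp_eval(R: float, k: float, A: float, B: float, C: float,
               t: "float | np.ndarray") -> "float | np.ndarray":
    """Biexponential decay M(t) = A exp(-R t) + B exp(-k t) + C."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-R * t) + B * np.exp(-k * t) + C


def fit_biexp_global(dataset: KineticsDataset, fit_offset: bool = True,
                     n_starts: int = 5) -> BiexpFitResult:
    """Global biexponential fit with R and k shared between both curves.

    The amplitudes (A, B and, optionally, the offset C) are free per curve;
    points are inverse-variance weighted when uncertainties are present.
    ``n_starts`` initializations log-spaced in k guard against local minima.
    Raises if fewer than six mixing times are available; a collapse of the
    two decay constants (|k - R| / k < 1e-3) is flagged as degenerate.
    """
    import lmfit

    if len(dataset) < 6:
        raise ValueError("global biexponential fit needs >= 6 time points")
    t = dataset.tau_e
    span = max(t[-1], 1e-9)

    def residual(params):
        R, k = params["R"].value, params["k"].value
        res = []
        for tag, M, sig in (("e", dataset.M_e, dataset.sigma_e),
                            ("f", dataset.M_f, dataset.sigma_f)):
            model = biexp_eval(R, k, params[f"A_{tag}"].value,
                               params[f"B_{tag}"].value,
                               params[f"C_{tag}"].value, t)
            r = M - model
            res.append(r / sig if sig is not None else r)
        return np.concatenate(res)

    scale = max(np.max(np.abs(dataset.M_e)), np.max(np.abs(dataset.M_f)))
    best = None
    for k0 in np.geomspace(0.1, 100.0, n_starts):
        params = lmfit.Parameters()
        params.add("R", value=0.1 / span, min=0.0)
        params.add("dk", value=max(k0 - 0.1 / span, 1e-6), min=1e-9)
        params.add("k", expr="R + dk")
        for tag, M in (("e", dataset.M_e), ("f", dataset.M_f)):
            params.add(f"A_{tag}", value=0.5 * M[0])
            params.add(f"B_{tag}", value=0.5 * (M[0] - M[-1]))
            params.add(f"C_{tag}", value=float(M[-1]) if fit_offset else 0.0,
                       vary=fit_offset)
        out = lmfit.minimize(residual, params, method="least_squares")
        sse = float(np.sum(out.residual ** 2))
        key = (round(sse, 12), out.params["k"].value)
        if best is None or key < best[0]:
            best = (key, out)
    out = best[1]
    p = out.params
    R, k = p["R"].value, p["k"].value
    degenerate = k > 0 and abs(k - R) / k < 1e-3
    if degenerate:
        warnings.warn("decay constants R and k collapsed; exchange rate "
                      "is not identifiable", DegenerateRatesWarning)
    amps = {f"{a}_{tag}": p[f"{a}_{tag}"].value
            for tag in ("e", "f") for a in ("A", "B", "C")}
    return BiexpFitResult(
        R=R, k=k,
        sigma_R=p["R"].stderr or float("nan"),
        sigma_k=_kerr(p), amplitudes=amps,
        covar=getattr(out, "covar", None),
        redchi=float(out.redchi), degenerate=degenerate)


def _kerr(p) -> float:
    # k = R + dk; combine the errors through the covariance when available
    if p["R"].stderr is None or p["dk"].stderr is None:
        return float("nan")
    cov = 0.0
    try:
        cov = p["R"].correl.get("dk", 0.0) * p["R"].stderr * p["dk"].stderr
    except AttributeError:
        pass
    return math.sqrt(max(p["R"].stderr ** 2 + p["dk"].stderr ** 2 + 2 * cov,
                         0.0))


def kd_from_eigenvalue(k: float, ratio_bound_to_free: float,
                       sigma_k: float = 0.0, sigma_ratio: float = 0.0
                       ) -> tuple[float, float]:
    """Dissociation rate constant from the fast exchange eigenvalue.

    k_d = k / (0.5 + r) with r = [CsS2]/[S], the bound-to-free
    concentration ratio (often far below one: many free ligands per
    complex).  Returns (k_d, sigma_kd) with first-order error propagation.
    """
    if k < 0 or ratio_bound_to_free < 0:
        raise ValueError("k and ratio must be non-negative")
    denom = 0.5 + ratio_bound_to_free
    k_d = k / denom
    var = (sigma_k / denom) ** 2 + (k / denom ** 2) ** 2 * sigma_ratio ** 2
    return k_d, math.sqrt(var)


# ---------------------------------------------------------------------------
# mechanistic models

def rate_matrix(model_id: str, system: ExchangeSystem) -> np.ndarray:
    """First-order rate matrix L of d/dt [pools] = L [pools].

    ``simplified`` (CsS2 <-> S2): pools (M_e, M_f),

        dM_e/dt = -(R_e + k_d/2) M_e + k_d r M_f
        dM_f/dt = +(k_d/2) M_e - (R_f + k_d r) M_f,   r = [CsS2]/[S].

    A dissociation event removes both equatorial ligands' magnetization
    from the complex pool only in the sense that one chosen ligand leaves
    at k_d/2 while re-association returns free magnetization at the
    steady-state flux k_d [CsS2], i.e. k_d r per unit of M_f.  With equal
    relaxation rates the eigenvalues are -R and -(R + k_d (0.5 + r)),
    which is the origin of the eigenvalue relation k = k_d (0.5 + r).

    ``full`` (CsS2 <-> CsS + S): adds the intermediate mono-substrate pool
    M_i.  Every dissociation (total flux k_d [CsS2]) sends one ligand to
    the free pool and parks the other on CsS; re-association (rate
    k_assoc, steady-state [CsS] = k_d [CsS2] / k_assoc) merges one
    intermediate-bound and one free ligand back into the complex:

        dM_e/dt = -(R_e + k_d) M_e + k_assoc M_i + k_d r M_f
        dM_i/dt = +(k_d/2) M_e - (R_e + k_assoc) M_i
        dM_f/dt = +(k_d/2) M_e - (R_f + k_d r) M_f

    which reduces to the simplified model as k_assoc -> infinity.
    """
    kd, r = system.k_d, system.ratio
    if model_id == "simplified":
        return np.array([
            [-(system.R_e + kd / 2.0), kd * r],
            [kd / 2.0, -(system.R_f + kd * r)],
        ])
    if model_id == "full":
        ka = system.k_assoc_eff
        return np.array([
            [-(system.R_e + kd), ka, kd * r],
            [kd / 2.0, -(system.R_e + ka), 0.0],
            [kd / 2.0, 0.0, -(system.R_f + kd * r)],
        ])
    raise ValueError(f"unknown model {model_id!r}; use 'simplified' or 'full'")


def simulate_model(model_id: str, system: ExchangeSystem, P_e0: float,
                   tau_e_grid: Sequence[float]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Bound and free magnetization curves on a mixing-time grid.

    The bound pool starts hyperpolarized at ``P_e0`` and the free pool at
    zero (at tau_e = 0 the free-substrate polarization is zero).  Solved
    exactly with the matrix exponential; with k > R > 0 the free curve
    rises to an interior maximum before relaxing away.
    """
    if not (P_e0 > 0):
        raise ValueError("P_e0 must be positive")
    L = rate_matrix(model_id, system)
    if not np.all(np.isfinite(L)):
        raise ValueError("rate matrix contains non-finite entries")
    y0 = np.zeros(L.shape[0])
    y0[0] = P_e0
    t = np.asarray(tau_e_grid, dtype=float)
    out = np.empty((t.size, L.shape[0]))
    w, V = np.linalg.eig(L)
    c = np.linalg.solve(V, y0)
    for i, ti in enumerate(t):
        out[i] = (V @ (c * np.exp(w * ti))).real
    return out[:, 0], out[:, -1]


def fit_model(dataset: KineticsDataset, model_id: str,
              ratio: float | None = None, fit_Re_Rf_separately: bool = False,
              n_starts: int = 5) -> ModelFitResult:
    """Least-squares fit of a mechanistic exchange model to both curves.

    Free parameters are (k_d, R, P_e0); the concentration ratio r is taken
    from the dataset (or the ``ratio`` argument) and held fixed, as it is
    measured independently from the 1H spectrum.  Multi-start trust-region
    least squares with ties broken by lowest SSE then lowest k_d.
    """
    import lmfit

    if model_id == "eigen":
        raise ValueError("use fit_biexp_global for the eigenvalue analysis")
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    r = dataset.ratio if ratio is None else float(ratio)
    if r is None:
        raise ValueError("dataset carries no concentration ratio")
    if not (1e-3 <= r <= 1e3):
        warnings.warn("extreme bound:free ratio; k_d may be poorly "
                      "identifiable", UserWarning)
    t = dataset.tau_e
    span = max(t[-1], 1e-9)

    def curves(params):
        sys_ = ExchangeSystem(
            k_d=params["k_d"].value, c_complex=r, c_free=1.0,
            R_e=params["R_e"].value,
            R_f=params["R_f"].value if fit_Re_Rf_separately
            else params["R_e"].value)
        return simulate_model(model_id, sys_, params["P_e0"].value, t)

    def residual(params):
        Me, Mf = curves(params)
        r_e = dataset.M_e - Me
        r_f = dataset.M_f - Mf
        if dataset.sigma_e is not None:
            r_e = r_e / dataset.sigma_e
        if dataset.sigma_f is not None:
            r_f = r_f / dataset.sigma_f
        return np.concatenate([r_e, r_f])

    best = None
    for k0 in np.geomspace(0.1, 100.0, n_starts):
        params = lmfit.Parameters()
        params.add("k_d", value=k0 / (0.5 + r), min=1e-9)
        params.add("R_e", value=0.1 / span, min=0.0)
        if fit_Re_Rf_separately:
            params.add("R_f", value=0.1 / span, min=0.0)
        params.add("P_e0", value=float(np.max(np.abs(dataset.M_e))),
                   min=1e-12)
        try:
            out = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        sse = float(np.sum(out.residual ** 2))
        key = (round(sse, 12), out.params["k_d"].value)
        if best is None or key < best[0]:
            best = (key, out)
    if best is None:
        raise RuntimeError("model fit failed to converge from any start")
    out = best[1]
    p = out.params
    return ModelFitResult(
        model_id=model_id, k_d=p["k_d"].value,
        sigma_kd=p["k_d"].stderr or float("nan"),
        R=p["R_e"].value, sigma_R=p["R_e"].stderr or float("nan"),
        P_e0=p["P_e0"].value, redchi=float(out.redchi),
        covar=getattr(out, "covar", None), residuals=out.residual)
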