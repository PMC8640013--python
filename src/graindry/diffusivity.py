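"""Effective moisture diffusivity from the Fick-sphere series, and Arrhenius analysis.

The falling-rate drying of a sphere of radius R with uniform initial
moisture, symmetric centre and negligible external resistance has the
series solution

    MR(t) = (6/pi^2) * sum_{n>=1} (1/n^2) exp(-D n^2 pi^2 t / R^2)

with t in seconds and the effective diffusivity D in m^2 s^-1.  Two
estimators are provided:

* method of slopes — linear regression of ln(MR) on t inside the
  first-term regime (MR below a configurable threshold, default 0.6),
  with D = -slope * R^2 / pi^2;
* full-series fit — one-parameter bounded least squares of the
  truncated series against the observed moisture ratio.

The temperature dependence of D follows the Arrhenius law
``D = A exp(-E / (R_gas T))`` with R_gas = 8314 J kmol^-1 K^-1 and the
activation energy E reported in kJ kmol^-1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from ._errors import ContractError, EstimationError
from .drying_models import MoistureRatioSeries

__all__ = [
    "GAS_CONSTANT_J_PER_KMOL_K",
    "DiffusivityEstimate",
    "ArrheniusFit",
    "fick_sphere_mr",
    "estimate_d_slopes",
    "estimate_d_series",
    "arrhenius_fit",
]

GAS_CONSTANT_J_PER_KMOL_K = 8314.0

_D_BOUNDS = (1e-13, 1e-7)


@dataclass(frozen=True)
class DiffusivityEstimate:
    """Effective diffusivity estimate with its provenance."""

    d_m2s: float
    method: str  # "slopes" | "series_fit"
    radius_m: float
    n_terms: int
    fit_r2_pct: float
    n_points: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.d_m2s <= 0 or self.radius_m <= 0 or self.n_terms < 1:
            raise ContractError("invalid diffusivity estimate fields")


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters for diffusivity against absolute temperature."""

    a_m2s: float
    e_kj_kmol: float
    points: tuple[tuple[float, float], ...]
    r2_pct: float
    gas_const: float = GAS_CONSTANT_J_PER_KMOL_K

    def predict(self, t_k: float | np.ndarray) -> np.ndarray:
        e_j = self.e_kj_kmol * 1000.0
        return self.a_m2s * np.exp(-e_j / (self.gas_const * np.asarray(t_k, float)))


def fick_sphere_mr(
    d_m2s: float,
    radius_m: float,
    t_s: Sequence[float] | np.ndarray,
    n_terms: int = 50,
) -> np.ndarray:
    """Truncated Fick-sphere series MR(t) for times in seconds."""
    if n_terms < 1:
        raise ContractError("n_terms must be >= 1")
    if d_m2s <= 0 or radius_m <= 0:
        raise ContractError("diffusivity and radius must be positive")
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ContractError("times must be non-negative")
    n = np.arange(1, n_terms + 1)
    # (T, N) exponent matrix; modest sizes only (N<=~1000)
    expo = -d_m2s * (n**2) * np.pi**2 / radius_m**2
    terms = np.exp(np.outer(t, expo)) / n**2
    return 6.0 / np.pi**2 * terms.sum(axis=1)


def _times_seconds(mr: MoistureRatioSeries) -> np.ndarray:
    return mr.time_h * 3600.0


def estimate_d_slopes(
    mr: MoistureRatioSeries,
    radius_m: float,
    mr_window: float = 0.6,
) -> DiffusivityEstimate:
    """Method of slopes: D = -slope(ln MR vs t) * R^2 / pi^2.

    Only points with 0 < MR < ``mr_window`` enter the regression; the
    window restricts the fit to the first-term regime of the series.
    """
    if radius_m <= 0:
        raise ContractError("radius must be positive")
    t = _times_seconds(mr)
    usable = (mr.mr > 0) & (mr.mr < mr_window)
    if usable.sum() < 3:
        raise ContractError(
            f"need >= 3 points with 0 < MR < {mr_window} for the slopes method"
        )
    reg = stats.linregress(t[usable], np.log(mr.mr[usable]))
    if reg.slope >= 0:
        raise EstimationError("non-negative ln(MR) slope: data do not show drying")
    d = -reg.slope * radius_m**2 / np.pi**2
    return DiffusivityEstimate(
        d_m2s=float(d),
        method="slopes",
        radius_m=float(radius_m),
        n_terms=1,
        fit_r2_pct=float(100.0 * reg.rvalue**2),
        n_points=int(usable.sum()),
    )


def estimate_d_series(
    mr: MoistureRatioSeries,
    radius_m: float,
    n_terms: int = 50,
    d_bounds: tuple[float, float] = _D_BOUNDS,
) -> DiffusivityEstimate:
    """Full-series fit: minimise SSE between observed MR and the truncated series.

    The single parameter D is optimised in log space over ``d_bounds``.
    """
    if radius_m <= 0:
        raise ContractError("radius must be positive")
    if n_terms < 1:
        raise ContractError("n_terms must be >= 1")
    if len(mr) == 0:
        raise ContractError("empty moisture-ratio series")
    t = _times_seconds(mr)
    y = mr.mr

    def sse_of_logd(logd: float) -> float:
        pred = fick_sphere_mr(10.0**logd, radius_m, t, n_terms)
        return float(np.sum((pred - y) ** 2))

    lo, hi = np.log10(d_bounds[0]), np.log10(d_bounds[1])
    sol = minimize_scalar(
        sse_of_logd, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    d = float(10.0**sol.x)
    pred = fick_sphere_mr(d, radius_m, t, n_terms)
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 100.0 * (1.0 - np.sum((y - pred) ** 2) / sstot) if sstot > 0 else np.nan
    return DiffusivityEstimate(
        d_m2s=d,
        method="series_fit",
        radius_m=float(radius_m),
        n_terms=int(n_terms),
        fit_r2_pct=float(r2) if np.isfinite(r2) else 0.0,
        n_points=len(mr),
        converged=bool(sol.success),
    )


def arrhenius_fit(points: Sequence[tuple[float, float]]) -> ArrheniusFit:
    """Fit D = A exp(-E/(R_gas T)) by linear regression of ln(D) on 1/T.

    ``points`` are (absolute temperature K, diffusivity m^2 s^-1) pairs;
    E is returned in kJ kmol^-1.
    """
    pts = [(float(t), float(d)) for t, d in points]
    if len(pts) < 2:
        raise ContractError("need >= 2 (T, D) points")
    t_k = np.array([p[0] for p in pts])
    d = np.array([p[1] for p in pts])
    if np.any(t_k <= 0) or np.any(d <= 0):
        raise ContractError("temperatures and diffusivities must be positive")
    if np.unique(t_k).size < 2:
        raise ContractError("need >= 2 distinct temperatures")
    inv_t = 1.0 / t_k
    ln_d = np.log(d)
    if np.allclose(ln_d, ln_d[0]):
        # flat line: zero activation energy, A equals the common D
        return ArrheniusFit(
            a_m2s=float(d[0]), e_kj_kmol=0.0, points=tuple(pts), r2_pct=100.0
        )
    reg = stats.linregress(inv_t, ln_d)
    e_kj_kmol = -reg.slope * GAS_CONSTANT_J_PER_KMOL_K / 1000.0
    return ArrheniusFit(
        a_m2s=float(np.exp(reg.intercept)),
        e_kj_kmol=float(e_kj_kmol),
        points=tuple(pts),
        r2_pct=float(100.0 * reg.rvalue**2),
    )
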