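"""Thin-layer drying curves: the moisture-ratio transform and the model registry.

The moisture ratio

    MR(t) = (X(t) - Xe) / (X0 - Xe)

normalises a dry-basis moisture record to start at 1 and decay towards 0
as the grain approaches its equilibrium moisture ``Xe``.  Eleven
semi-empirical and empirical thin-layer models are registered here, each
a closed form MR(t) with time in hours and rate constants in h^-1:

================================  =============================================
newton                            exp(-k t)
page                              exp(-k t^n)
page_modified                     exp(-(k t)^n)
henderson_pabis                   a exp(-k t)
logarithmic                       a exp(-k t) + c
two_terms                         a exp(-k0 t) + b exp(-k1 t)
two_exponential_terms             a exp(-k t) + (1 - a) exp(-k a t)
wang_singh                        1 + a t + b t^2
henderson_pabis_modified          a exp(-k t) + b exp(-k0 t) + c exp(-k1 t)
midilli                           a exp(-k t^n) + b t
diffusion_approximation           a exp(-k t) + (1 - a) exp(-k b t)
================================  =============================================
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._errors import ConfigurationError, ContractError
from .models import ModelSpec

__all__ = [
    "DryingCurve",
    "MoistureRatioSeries",
    "DRYING_MODELS",
    "get_drying_model",
    "moisture_ratio",
    "evaluate_model",
]

# ---------------------------------------------------------------------------
# domain containers

_MOISTURE_TOL = 1e-6


@dataclass(frozen=True)
class DryingCurve:
    """Time-ordered dry-basis moisture record for one drying run.

    ``time_h`` must be strictly increasing and start at zero; moisture is
    a dry-basis decimal fraction in (0, 1); the first moisture value must
    equal the stated initial moisture ``x0`` within a small tolerance.
    """

    time_h: np.ndarray
    moisture_db: np.ndarray
    air_temp_C: float
    x0: float
    xe: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        m = np.asarray(self.moisture_db, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "moisture_db", m)
        if t.ndim != 1 or m.shape != t.shape:
            raise ContractError("time_h and moisture_db must be 1-D of equal length")
        if t.size == 0:
            raise ContractError("empty drying curve")
        if t[0] != 0:
            raise ContractError("time must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ContractError("time must be strictly increasing")
        if np.any((m <= 0) | (m >= 1)):
            raise ContractError("moisture (d.b. decimal) must lie in (0, 1)")
        if abs(m[0] - self.x0) > 1e-3 + _MOISTURE_TOL:
            raise ContractError(
                f"first moisture value {m[0]:.4f} does not match x0={self.x0:.4f}"
            )
        if self.xe is not None and self.xe >= m.min():
            raise ContractError("xe must lie below every observed moisture value")

    def __len__(self) -> int:
        return int(self.time_h.size)


@dataclass(frozen=True)
class MoistureRatioSeries:
    """Dimensionless moisture-ratio record on the same time grid."""

    time_h: np.ndarray
    mr: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        r = np.asarray(self.mr, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "mr", r)
        if t.ndim != 1 or r.shape != t.shape:
            raise ContractError("time_h and mr must be 1-D of equal length")
        if np.any((r < -0.05) | (r > 1.05)):
            raise ContractError("moisture ratio outside [-0.05, 1.05]")

    def __len__(self) -> int:
        return int(self.time_h.size)


# ---------------------------------------------------------------------------
# model registry


def _newton(t, k):
    return np.exp(-k * t)


def _page(t, k, n):
    return np.exp(-k * np.power(t, n))


def _page_modified(t, k, n):
    return np.exp(-np.power(k * t, n))


def _henderson_pabis(t, a, k):
    return a * np.exp(-k * t)


def _logarithmic(t, a, k, c):
    return a * np.exp(-k * t) + c


def _two_terms(t, a, k0, b, k1):
    return a * np.exp(-k0 * t) + b * np.exp(-k1 * t)


def _two_exponential_terms(t, a, k):
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-k * a * t)


def _wang_singh(t, a, b):
    return 1.0 + a * t + b * t * t


def _henderson_pabis_modified(t, a, k, b, k0, c, k1):
    return a * np.exp(-k * t) + b * np.exp(-k0 * t) + c * np.exp(-k1 * t)


def _midilli(t, a, k, n, b):
    return a * np.exp(-k * np.power(t, n)) + b * t


def _diffusion_approximation(t, a, k, b):
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-k * b * t)


_K_BOUNDS = (1e-6, 1e3)
_N_BOUNDS = (1e-6, 10.0)
_COEF_BOUNDS = (-50.0, 50.0)


def _bounds_for(names: Sequence[str]) -> dict[str, tuple[float, float]]:
    out = {}
    for p in names:
        if p in ("k", "k0", "k1"):
            out[p] = _K_BOUNDS
        elif p == "n":
            out[p] = _N_BOUNDS
        else:
            out[p] = _COEF_BOUNDS
    return out


def _spec(name, names, func, init):
    return ModelSpec(
        name=name,
        param_names=tuple(names),
        bounds=_bounds_for(names),
        default_init=dict(init),
        func=func,
    )


DRYING_MODELS: dict[str, ModelSpec] = {
    s.name: s
    for s in (
        _spec("newton", ("k",), _newton, {"k": 0.5}),
        _spec("page", ("k", "n"), _page, {"k": 0.5, "n": 1.0}),
        _spec("page_modified", ("k", "n"), _page_modified, {"k": 0.5, "n": 1.0}),
        _spec("henderson_pabis", ("a", "k"), _henderson_pabis, {"a": 1.0, "k": 0.5}),
        _spec(
            "logarithmic",
            ("a", "k", "c"),
            _logarithmic,
            {"a": 1.0, "k": 0.5, "c": 0.0},
        ),
        _spec(
            "two_terms",
            ("a", "k0", "b", "k1"),
            _two_terms,
            {"a": 0.6, "k0": 0.3, "b": 0.4, "k1": 1.2},
        ),
        _spec(
            "two_exponential_terms",
            ("a", "k"),
            _two_exponential_terms,
            {"a": 1.5, "k": 0.5},
        ),
        _spec("wang_singh", ("a", "b"), _wang_singh, {"a": -0.3, "b": 0.02}),
        _spec(
            "henderson_pabis_modified",
            ("a", "k", "b", "k0", "c", "k1"),
            _henderson_pabis_modified,
            {"a": 0.4, "k": 0.3, "b": 0.3, "k0": 0.7, "c": 0.3, "k1": 1.4},
        ),
        _spec(
            "midilli",
            ("a", "k", "n", "b"),
            _midilli,
            {"a": 1.0, "k": 0.5, "n": 1.0, "b": 0.0},
        ),
        _spec(
            "diffusion_approximation",
            ("a", "k", "b"),
            _diffusion_approximation,
            {"a": 0.6, "k": 0.5, "b": 1.5},
        ),
    )
}


def get_drying_model(name: str) -> ModelSpec:
    try:
        return DRYING_MODELS[name]
    except KeyError:
        raise ContractError(
            f"unknown drying model {name!r}; known: {sorted(DRYING_MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# operations


def resolve_xe(curve: DryingCurve, fallback_factor: float = 0.9) -> float:
    """Equilibrium moisture for a curve.

    Uses the curve's own ``xe`` when present; otherwise falls back to
    ``fallback_factor * min(moisture)`` with a warning, which keeps the
    moisture ratio well defined without assuming a sorption isotherm.
    """
    if curve.xe is not None:
        return float(curve.xe)
    xe = fallback_factor * float(curve.moisture_db.min())
    warnings.warn(
        f"curve {curve.label!r}: xe not supplied, using "
        f"{fallback_factor} * min(moisture) = {xe:.4f}",
        stacklevel=2,
    )
    return xe


def moisture_ratio(curve: DryingCurve, xe: float | None = None) -> MoistureRatioSeries:
    """Moisture ratio MR = (X - Xe)/(X0 - Xe) for a drying curve.

    Moisture values at or below ``Xe`` (noisy tails) are clipped to
    MR = 0 with a warning rather than rejected.
    """
    xe_val = float(xe) if xe is not None else resolve_xe(curve)
    if curve.x0 <= xe_val:
        raise ConfigurationError(
            f"x0={curve.x0} must exceed xe={xe_val} for the moisture ratio"
        )
    mr = (curve.moisture_db - xe_val) / (curve.x0 - xe_val)
    if np.any(mr < 0):
        warnings.warn(
            f"{int(np.sum(mr < 0))} moisture value(s) below xe; clipping MR to 0",
            stacklevel=2,
        )
        mr = np.clip(mr, 0.0, None)
    return MoistureRatioSeries(time_h=curve.time_h.copy(), mr=mr)


def evaluate_model(
    spec: ModelSpec | str,
    params: Mapping[str, float],
    t: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Closed-form moisture ratio of a registered drying model at times ``t`` (h)."""
    if isinstance(spec, str):
        spec = get_drying_model(spec)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ContractError("drying time must be non-negative")
    return spec.evaluate(params, t_arr)
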