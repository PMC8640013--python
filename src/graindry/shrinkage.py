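"""Grain volume and unit volumetric shrinkage models.

The grain is measured along three orthogonal axes and treated as an
ellipsoid, ``V = pi a b c / 6``.  Unit shrinkage ``psi`` is the volume at
a given moisture divided by the initial volume, and six empirical
closed forms describe psi as a function of dry-basis moisture ``X``
(with ``X0`` the initial moisture):

=================  ========================================
bala_woods         a * (1 - exp(b (X - X0)))
lang_sokhansanj    a + beta1 (X - X0)
rahman             a + beta2 (X - X0)
correa             1 / (a + b exp(X))
line               a + b X
exponential        a exp(b X)
=================  ========================================

``lang_sokhansanj`` and ``rahman`` share the linear-in-(X - X0) form;
the former's slope beta1 is, in full generality, a + b*UR + c*T (relative
humidity and air-temperature covariates), but it is fitted here as a
single free scalar since one slope is reported per drying condition.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._errors import ContractError, DomainError
from .models import ModelSpec

__all__ = [
    "GrainAxes",
    "ShrinkageSeries",
    "SHRINKAGE_MODELS",
    "get_shrinkage_model",
    "grain_volume",
    "unit_shrinkage",
    "evaluate_shrinkage_model",
    "equivalent_sphere_radius_m",
]


@dataclass(frozen=True)
class GrainAxes:
    """Tri-axial grain dimensions in millimetres, major >= mean >= minor."""

    a_mm: float
    b_mm: float
    c_mm: float

    def __post_init__(self) -> None:
        if min(self.a_mm, self.b_mm, self.c_mm) <= 0:
            raise ContractError("grain axes must be positive")
        if not (self.a_mm >= self.b_mm >= self.c_mm):
            raise ContractError("axes must satisfy a_mm >= b_mm >= c_mm")


@dataclass(frozen=True)
class ShrinkageSeries:
    """Unit volume ratio psi against dry-basis moisture (decreasing)."""

    moisture_db: np.ndarray
    psi: np.ndarray
    x0: float

    def __post_init__(self) -> None:
        m = np.asarray(self.moisture_db, dtype=float)
        p = np.asarray(self.psi, dtype=float)
        object.__setattr__(self, "moisture_db", m)
        object.__setattr__(self, "psi", p)
        if m.ndim != 1 or p.shape != m.shape or m.size == 0:
            raise ContractError("moisture_db and psi must be 1-D of equal length")
        if np.any(np.diff(m) >= 0):
            raise ContractError("moisture must be strictly decreasing during drying")

    def validate_physical(self, tol: float = 0.05) -> list[str]:
        """Soft physical checks; returns warnings instead of raising.

        Published parameter sets are sometimes internally inconsistent
        (e.g. psi(X0) far from 1); such series are still representable
        for parameter-recovery work, so violations only warn.
        """
        issues = []
        at_x0 = np.isclose(self.moisture_db, self.x0, atol=1e-9)
        if at_x0.any() and abs(self.psi[at_x0][0] - 1.0) > tol:
            issues.append(
                f"psi at X0 is {self.psi[at_x0][0]:.4f}, expected ~1"
            )
        if np.any((self.psi <= 0) | (self.psi > 1.2)):
            issues.append("psi values outside the physical range (0, 1.2]")
        for msg in issues:
            warnings.warn(msg, stacklevel=2)
        return issues

    def __len__(self) -> int:
        return int(self.moisture_db.size)


# ---------------------------------------------------------------------------
# registry


def _bala_woods(x, a, b, x0=0.0):
    return a * (1.0 - np.exp(b * (x - x0)))


def _lang_sokhansanj(x, a, beta1, x0=0.0):
    return a + beta1 * (x - x0)


def _rahman(x, a, beta2, x0=0.0):
    return a + beta2 * (x - x0)


def _correa(x, a, b, x0=0.0):
    # invalid region mapped to a large penalty so optimisers and grid
    # oracles can traverse it; the public wrapper raises instead
    denom = a + b * np.exp(x)
    with np.errstate(divide="ignore"):
        out = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), 1e6)
    return out


def _line(x, a, b, x0=0.0):
    return a + b * x


def _exponential(x, a, b, x0=0.0):
    return a * np.exp(b * x)


_COEF_BOUNDS = (-50.0, 50.0)


def _sspec(name, names, func, init):
    return ModelSpec(
        name=name,
        param_names=tuple(names),
        bounds={p: _COEF_BOUNDS for p in names},
        default_init=dict(init),
        func=func,
        fixed_names=("x0",),
    )


SHRINKAGE_MODELS: dict[str, ModelSpec] = {
    s.name: s
    for s in (
        _sspec("bala_woods", ("a", "b"), _bala_woods, {"a": 1.0, "b": -10.0}),
        _sspec(
            "lang_sokhansanj", ("a", "beta1"), _lang_sokhansanj, {"a": 1.0, "beta1": 1.0}
        ),
        _sspec("rahman", ("a", "beta2"), _rahman, {"a": 1.0, "beta2": 1.0}),
        _sspec("correa", ("a", "b"), _correa, {"a": 0.7, "b": 1.0}),
        _sspec("line", ("a", "b"), _line, {"a": 1.0, "b": 1.0}),
        _sspec("exponential", ("a", "b"), _exponential, {"a": 0.7, "b": 1.0}),
    )
}


def get_shrinkage_model(name: str) -> ModelSpec:
    try:
        return SHRINKAGE_MODELS[name]
    except KeyError:
        raise ContractError(
            f"unknown shrinkage model {name!r}; known: {sorted(SHRINKAGE_MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# operations


def grain_volume(axes: GrainAxes) -> float:
    """Ellipsoid grain volume V = pi*a*b*c/6 in mm^3."""
    return float(np.pi * axes.a_mm * axes.b_mm * axes.c_mm / 6.0)


def unit_shrinkage(volumes: Sequence[float] | np.ndarray) -> np.ndarray:
    """Each volume divided by the first; the first element is exactly 1."""
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ContractError("empty volume sequence")
    if np.any(v <= 0):
        raise ContractError("volumes must be positive")
    return v / v[0]


def evaluate_shrinkage_model(
    spec: ModelSpec | str,
    params: Mapping[str, float],
    moisture_db: Sequence[float] | np.ndarray,
    x0: float,
) -> np.ndarray:
    """Closed-form psi of a registered shrinkage model at the given moistures."""
    if isinstance(spec, str):
        spec = get_shrinkage_model(spec)
    m = np.asarray(moisture_db, dtype=float)
    if spec.name == "correa":
        spec.check_params(params)
        if np.any(params["a"] + params["b"] * np.exp(m) <= 0):
            raise DomainError("correa model: a + b*exp(X) must stay positive")
    return spec.evaluate(params, m, x0=float(x0))


def equivalent_sphere_radius_m(axes: GrainAxes) -> float:
    """Geometric-mean radius (a*b*c)^(1/3) / 2, converted from mm to m.

    The diffusion solution assumes a sphere; this radius preserves the
    grain volume of the ellipsoid approximation.
    """
    return float((axes.a_mm * axes.b_mm * axes.c_mm) ** (1.0 / 3.0) / 2.0 / 1000.0)
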