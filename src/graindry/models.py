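"""Shared model-specification machinery for the closed-form model registries.

A :class:`ModelSpec` bundles a model's closed form with its parameter
names, box bounds and default starting values, so the fitting engine can
treat every drying and shrinkage model uniformly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._errors import ContractError

__all__ = ["ModelSpec"]


@dataclass(frozen=True)
class ModelSpec:
    """Closed-form model with named, bounded parameters.

    Parameters
    ----------
    name
        Registry key, e.g. ``"newton"``.
    param_names
        Ordered parameter identifiers matching the published equation.
    bounds
        Per-parameter ``(lower, upper)`` box constraints.
    default_init
        Per-parameter starting values for the optimiser.
    func
        Vectorised callable ``func(x, *params, **fixed)`` evaluating the
        closed form; ``fixed`` carries non-fitted quantities such as the
        initial moisture of a shrinkage series.
    fixed_names
        Names of the required fixed quantities (may be empty).
    """

    name: str
    param_names: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    default_init: Mapping[str, float]
    func: Callable[..., np.ndarray]
    fixed_names: tuple[str, ...] = field(default=())

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def check_params(self, params: Mapping[str, float]) -> None:
        missing = set(self.param_names) - set(params)
        extra = set(params) - set(self.param_names)
        if missing or extra:
            raise ContractError(
                f"model {self.name!r}: parameter mismatch "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )

    def param_vector(self, params: Mapping[str, float]) -> np.ndarray:
        self.check_params(params)
        return np.array([float(params[p]) for p in self.param_names])

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[p][0] for p in self.param_names])
        hi = np.array([self.bounds[p][1] for p in self.param_names])
        return lo, hi

    def evaluate(
        self,
        params: Mapping[str, float],
        x: Sequence[float] | np.ndarray,
        **fixed: float,
    ) -> np.ndarray:
        """Evaluate the closed form at ``x`` with a complete parameter map."""
        vec = self.param_vector(params)
        missing_fixed = set(self.fixed_names) - set(fixed)
        if missing_fixed:
            raise ContractError(
                f"model {self.name!r}: missing fixed quantities {sorted(missing_fixed)}"
            )
        return self.evaluate_vector(vec, np.asarray(x, dtype=float), **fixed)

    def evaluate_vector(
        self, vec: np.ndarray, x: np.ndarray, **fixed: float
    ) -> np.ndarray:
        return np.asarray(self.func(x, *vec, **fixed), dtype=float)
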