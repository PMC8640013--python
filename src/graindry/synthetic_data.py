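"""Seeded generators for drying, shrinkage, diffusion and storage-quality data.

Every generator is a pure function of its configuration and seed.  The
drying/shrinkage/diffusion generators invert the corresponding closed
forms and add independent Gaussian measurement noise on the observed
scale.  The storage generator emulates the full factorial of a storage
trial — 2 harvest moistures x 4 drying temperatures (including a mixed
batch) x 3 storage temperatures x 2 package types x 3 sampling months x
3 replicates = 432 records — with an additive effect structure:

    value = baseline + storage-severity effect + month trend
            + drying-temperature offset + harvest offset
            + package offset + noise

The storage-severity effect is the planted group structure: the six
(storage temperature, package) cells map to four ordered severity
tiers (15 C best, 30 C in permeable paper worst), with gaps chosen
large relative to the secondary effects so the planted partition is
identifiable by clustering.  Oil and protein fall, conductivity and
acidity rise, with both severity and storage time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ContractError
from .drying_models import DryingCurve, MoistureRatioSeries, evaluate_model
from .diffusivity import fick_sphere_mr
from .shrinkage import ShrinkageSeries, evaluate_shrinkage_model
from .storage_multivariate import QUALITY_VARIABLES

__all__ = [
    "StorageEffectConfig",
    "SEVERITY_TIERS",
    "gen_drying_curve",
    "gen_shrinkage_series",
    "gen_fick_curve",
    "gen_storage_table",
    "planted_labels",
]

# (storage_temp_C, package) -> severity tier 0 (mild) .. 3 (severe)
SEVERITY_TIERS: dict[tuple[int, str], int] = {
    (15, "PL"): 0,
    (15, "P"): 0,
    (23, "PL"): 1,
    (23, "P"): 2,
    (30, "PL"): 2,
    (30, "P"): 3,
}

_HARVESTS = (23, 18)
_DRYING = ("80", "100", "120", "mixed")
_STORAGE = (15, 23, 30)
_PACKAGES = ("P", "PL")
_MONTHS = (0, 4, 8)


def _default_baselines():
    return {
        "moisture_pct": 10.31,
        "ec": 191.0,
        "oil_pct": 25.89,
        "acidity_ml": 5.54,
        "protein_pct": 35.69,
    }


def _default_tier_effects():
    return {
        "moisture_pct": (0.0, 0.0, 0.15, 0.45),
        "ec": (0.0, 70.0, 140.0, 210.0),
        "oil_pct": (0.0, -2.5, -5.0, -7.5),
        "acidity_ml": (0.0, 0.8, 1.6, 2.4),
        "protein_pct": (0.0, -3.0, -6.0, -9.0),
    }


def _default_time_slopes():
    return {
        "moisture_pct": 0.01,
        "ec": 1.2,
        "oil_pct": -0.08,
        "acidity_ml": 0.03,
        "protein_pct": -0.12,
    }


def _default_drying_offsets():
    return {
        "moisture_pct": {"80": 0.0, "100": -0.04, "120": 0.045, "mixed": -0.10},
        "ec": {"80": 0.0, "100": 4.5, "120": 8.5, "mixed": 7.0},
        "oil_pct": {"80": 0.0, "100": -0.85, "120": -1.28, "mixed": -0.90},
        "acidity_ml": {"80": 0.0, "100": 0.11, "120": 0.31, "mixed": 0.04},
        "protein_pct": {"80": 0.0, "100": -0.65, "120": -1.07, "mixed": -0.51},
    }


def _default_harvest_offsets():
    # applied to the 18 % harvest relative to the 23 % reference
    return {
        "moisture_pct": -0.055,
        "ec": 4.0,
        "oil_pct": -0.89,
        "acidity_ml": 0.105,
        "protein_pct": -0.345,
    }


def _default_package_offsets():
    # applied to the permeable paper bag relative to polyethylene
    return {
        "moisture_pct": -0.05,
        "ec": 3.0,
        "oil_pct": -0.1,
        "acidity_ml": 0.03,
        "protein_pct": -0.15,
    }


def _default_noise_sd():
    return {
        "moisture_pct": 0.08,
        "ec": 3.0,
        "oil_pct": 0.12,
        "acidity_ml": 0.05,
        "protein_pct": 0.15,
    }


@dataclass
class StorageEffectConfig:
    """Effect structure of the synthetic storage factorial.

    Baselines are the reference treatment (23 % harvest, 80 C drying,
    mildest storage, month 0); all other effects are additive offsets.
    """

    baselines: dict[str, float] = field(default_factory=_default_baselines)
    tier_effects: dict[str, tuple] = field(default_factory=_default_tier_effects)
    time_slopes: dict[str, float] = field(default_factory=_default_time_slopes)
    drying_offsets: dict[str, dict] = field(default_factory=_default_drying_offsets)
    harvest_offsets: dict[str, float] = field(default_factory=_default_harvest_offsets)
    package_offsets: dict[str, float] = field(default_factory=_default_package_offsets)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for var in QUALITY_VARIABLES:
            if self.noise_sd[var] < 0:
                raise ContractError(f"noise SD for {var!r} must be >= 0")
        if self.time_slopes["oil_pct"] > 0 or self.time_slopes["protein_pct"] > 0:
            raise ContractError("oil and protein must not increase with storage time")
        if self.time_slopes["ec"] < 0 or self.time_slopes["acidity_ml"] < 0:
            raise ContractError(
                "conductivity and acidity must not decrease with storage time"
            )
        if self.n_replicates < 1:
            raise ContractError("need >= 1 replicate")


# ---------------------------------------------------------------------------
# kinetics generators


def gen_drying_curve(
    model: str,
    params: Mapping[str, float],
    x0: float,
    xe: float,
    duration_h: float,
    interval_h: float = 0.25,
    noise_sd: float = 0.0,
    seed: int = 0,
    air_temp_C: float = 80.0,
    label: str = "",
) -> DryingCurve:
    """Drying curve sampled on a regular grid from a registered model.

    The model's moisture ratio is inverted to dry-basis moisture via
    ``X = Xe + MR * (X0 - Xe)``; Gaussian noise (SD on the moisture
    scale) is added to every sample except t = 0, and values are kept
    inside ``(xe, x0]``.
    """
    if duration_h <= 0 or interval_h <= 0:
        raise ContractError("duration and interval must be positive")
    if noise_sd < 0:
        raise ContractError("noise_sd must be >= 0")
    if not 0 < xe < x0 < 1:
        raise ContractError("need 0 < xe < x0 < 1 (d.b. decimal)")
    t = np.arange(0.0, duration_h + 1e-9, interval_h)
    mr = evaluate_model(model, params, t)
    moisture = xe + mr * (x0 - xe)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=t.size)
        noise[0] = 0.0
        moisture = np.clip(moisture + noise, xe + 1e-6, x0)
    return DryingCurve(
        time_h=t,
        moisture_db=moisture,
        air_temp_C=air_temp_C,
        x0=x0,
        xe=xe,
        label=label or f"synthetic-{model}",
    )


def gen_shrinkage_series(
    model: str,
    params: Mapping[str, float],
    x0: float,
    x_final: float,
    n_points: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ShrinkageSeries:
    """Shrinkage series on a uniform moisture grid from ``x0`` down to ``x_final``."""
    if not 0 <= x_final < x0:
        raise ContractError("need 0 <= x_final < x0")
    if n_points < 2:
        raise ContractError("need >= 2 points")
    if noise_sd < 0:
        raise ContractError("noise_sd must be >= 0")
    moisture = np.linspace(x0, x_final, n_points)
    psi = evaluate_shrinkage_model(model, params, moisture, x0=x0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        psi = psi + rng.normal(0.0, noise_sd, size=n_points)
    return ShrinkageSeries(moisture_db=moisture, psi=psi, x0=x0)


def gen_fick_curve(
    d_m2s: float,
    radius_m: float,
    duration_s: float,
    interval_s: float = 300.0,
    n_terms: int = 1000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MoistureRatioSeries:
    """Moisture-ratio curve from the truncated Fick-sphere series."""
    if duration_s <= 0 or interval_s <= 0:
        raise ContractError("duration and interval must be positive")
    if noise_sd < 0:
        raise ContractError("noise_sd must be >= 0")
    t_s = np.arange(0.0, duration_s + 1e-9, interval_s)
    mr = fick_sphere_mr(d_m2s, radius_m, t_s, n_terms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mr = np.clip(mr + rng.normal(0.0, noise_sd, size=t_s.size), 0.0, 1.05)
    return MoistureRatioSeries(time_h=t_s / 3600.0, mr=mr)


# ---------------------------------------------------------------------------
# storage factorial


def gen_storage_table(config: StorageEffectConfig | None = None) -> pd.DataFrame:
    """Full storage-quality factorial with planted group structure.

    Returns 2 x 4 x 3 x 2 x 3 x n_replicates records (432 at default
    replication), reproducible for a given config and seed.
    """
    cfg = config or StorageEffectConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for harvest in _HARVESTS:
        for drying in _DRYING:
            for storage in _STORAGE:
                for package in _PACKAGES:
                    tier = SEVERITY_TIERS[(storage, package)]
                    for months in _MONTHS:
                        means = {}
                        for var in QUALITY_VARIABLES:
                            v = cfg.baselines[var]
                            v += cfg.tier_effects[var][tier]
                            v += cfg.time_slopes[var] * months
                            v += cfg.drying_offsets[var][drying]
                            if harvest == 18:
                                v += cfg.harvest_offsets[var]
                            if package == "P":
                                v += cfg.package_offsets[var]
                            means[var] = v
                        for rep in range(1, cfg.n_replicates + 1):
                            rec = {
                                "harvest_moisture_pct": harvest,
                                "drying_temp": drying,
                                "storage_temp_C": storage,
                                "package": package,
                                "time_months": months,
                                "replicate": rep,
                            }
                            for var in QUALITY_VARIABLES:
                                sd = cfg.noise_sd[var]
                                val = means[var] + (
                                    rng.normal(0.0, sd) if sd > 0 else 0.0
                                )
                                rec[var] = max(val, 1e-6)
                            rows.append(rec)
    return pd.DataFrame(rows)


def planted_labels(treatment_index: Sequence[str]) -> np.ndarray:
    """Planted severity tier (0..3) for each treatment id.

    Treatment ids follow the ``harvest/drying/storage/package/mMonths``
    convention of :func:`graindry.storage_multivariate.treatment_means`.
    """
    labels = []
    for tid in treatment_index:
        parts = str(tid).split("/")
        if len(parts) != 5:
            raise ContractError(f"unrecognised treatment id {tid!r}")
        storage = int(parts[2])
        package = parts[3]
        labels.append(SEVERITY_TIERS[(storage, package)])
    return np.asarray(labels, dtype=int)
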