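"""End-to-end analysis pipelines tying the stages together.

``run_drying_pipeline`` takes drying curves through the moisture-ratio
transform, fits every configured thin-layer model, ranks them and
reports the statistics; ``run_storage_pipeline`` takes a storage
factorial through standardisation, Ward clustering, per-group Pearson
correlations and Tukey letter tables.  Both embed their configuration
in the report so runs are reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._errors import ContractError
from .drying_models import DRYING_MODELS, DryingCurve, get_drying_model, moisture_ratio
from .fit_engine import fit_model, rank_models
from .storage_multivariate import (
    QUALITY_VARIABLES,
    cluster_correlations,
    standardize,
    treatment_means,
    tukey_letters,
    ward_cluster,
)

logger = logging.getLogger("graindry")

__all__ = ["PipelineConfig", "run_drying_pipeline", "run_storage_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs shared by the command-line pipelines."""

    models: tuple[str, ...] = tuple(sorted(DRYING_MODELS))
    alpha_levels: tuple[float, float] = (0.01, 0.05)
    p_threshold: float = 10.0
    slopes_mr_window: float = 0.6
    series_n_terms: int = 50
    cluster_k: int = 4
    cluster_variables: tuple[str, ...] = QUALITY_VARIABLES
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < a < 1 for a in self.alpha_levels):
            raise ContractError("alpha levels must lie in (0, 1)")
        if self.cluster_k < 1:
            raise ContractError("cluster_k must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_drying_pipeline(
    curves: Sequence[DryingCurve], config: PipelineConfig | None = None
) -> dict:
    """Fit all configured models to each curve and rank them."""
    cfg = config or PipelineConfig()
    report: dict = {"config": asdict(cfg), "config_hash": cfg.digest(), "curves": []}
    for curve in curves:
        logger.info("fitting %d models to curve %r", len(cfg.models), curve.label)
        mr = moisture_ratio(curve)
        results = []
        for name in cfg.models:
            spec = get_drying_model(name)
            res = fit_model(
                mr.time_h,
                mr.mr,
                spec,
                n_starts=cfg.n_starts,
                seed=cfg.seed,
                p_threshold=cfg.p_threshold,
            )
            if res.at_bounds:
                logger.warning(
                    "curve %r model %s converged on bound(s): %s",
                    curve.label, name, res.at_bounds,
                )
            results.append(res)
        ranked = rank_models(results, p_threshold=cfg.p_threshold)
        report["curves"].append(
            {
                "label": curve.label,
                "air_temp_C": curve.air_temp_C,
                "x0": curve.x0,
                "xe": curve.xe,
                "n_obs": len(curve),
                "ranking": [
                    dict(rank=i + 1, verdict=verdict, **res.to_row())
                    for i, (res, verdict) in enumerate(ranked)
                ],
                "best_model": ranked[0][0].model_name,
            }
        )
    return report


def run_storage_pipeline(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """Standardise, cluster and summarise a storage-quality factorial."""
    cfg = config or PipelineConfig()
    means = treatment_means(table, variables=cfg.cluster_variables)
    z = standardize(means)
    logger.info("clustering %d treatments into k=%d groups", len(means), cfg.cluster_k)
    clusters = ward_cluster(z, cfg.cluster_k)
    correlations = cluster_correlations(means, clusters.labels)
    letters = {}
    for var in cfg.cluster_variables:
        letters[var] = tukey_letters(
            table, response=var, factor="storage_temp_C",
            alpha=cfg.alpha_levels[1],
        ).to_dict(orient="records")
    return {
        "config": asdict(cfg),
        "config_hash": cfg.digest(),
        "n_records": int(len(table)),
        "n_treatments": int(len(means)),
        "labels": {
            tid: int(lab)
            for tid, lab in zip(clusters.treatment_ids, clusters.labels)
        },
        "merge_heights": clusters.merge_heights.tolist(),
        "group_correlations": {
            str(lab): corr.round(6).to_dict() for lab, corr in correlations.items()
        },
        "tukey_letters_by_storage_temp": letters,
    }


def write_report(report: dict, out_dir: str | Path, stem: str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{stem}.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return path
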