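"""CSV dialects and report serialisation.

Drying CSV:    ``time_h,moisture_db[,replicate]`` with ``#`` comments.
Shrinkage CSV: ``moisture_db,psi`` or ``moisture_db,a_mm,b_mm,c_mm``.
Storage CSV:   the full factorial schema of
               :mod:`graindry.storage_multivariate`.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import SchemaError
from .drying_models import DryingCurve
from .shrinkage import GrainAxes, ShrinkageSeries, grain_volume, unit_shrinkage
from .storage_multivariate import validate_storage_table


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV ({exc})") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    return df


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based indexing
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = vals


def read_drying_csv(
    path: str | Path,
    x0: float | None = None,
    xe: float | None = None,
    air_temp_C: float = np.nan,
    label: str | None = None,
) -> DryingCurve:
    """Load a drying curve; replicate columns, if present, are averaged."""
    path = Path(path)
    df = _read_csv(path, ["time_h", "moisture_db"])
    _check_numeric(df, ["time_h", "moisture_db"], path)
    if "replicate" in df.columns:
        df = df.groupby("time_h", as_index=False)["moisture_db"].mean()
    df = df.sort_values("time_h")
    m = df["moisture_db"].to_numpy(dtype=float)
    return DryingCurve(
        time_h=df["time_h"].to_numpy(dtype=float),
        moisture_db=m,
        air_temp_C=air_temp_C,
        x0=float(x0) if x0 is not None else float(m[0]),
        xe=xe,
        label=label or path.stem,
    )


def read_shrinkage_csv(path: str | Path, x0: float | None = None) -> ShrinkageSeries:
    """Load a shrinkage series, reducing raw axes to psi when necessary."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "psi" in df.columns:
        _check_numeric(df, ["moisture_db", "psi"], path)
        psi = df["psi"].to_numpy(dtype=float)
    elif {"a_mm", "b_mm", "c_mm"} <= set(df.columns):
        _check_numeric(df, ["moisture_db", "a_mm", "b_mm", "c_mm"], path)
        volumes = [
            grain_volume(GrainAxes(r.a_mm, r.b_mm, r.c_mm))
            for r in df.itertuples()
        ]
        psi = unit_shrinkage(volumes)
    else:
        raise SchemaError(
            f"{path}: need either a 'psi' column or 'a_mm','b_mm','c_mm'"
        )
    m = df["moisture_db"].to_numpy(dtype=float)
    return ShrinkageSeries(
        moisture_db=m, psi=psi, x0=float(x0) if x0 is not None else float(m[0])
    )


def read_storage_csv(path: str | Path) -> pd.DataFrame:
    df = _read_csv(
        path,
        [
            "harvest_moisture_pct",
            "drying_temp",
            "storage_temp_C",
            "package",
            "time_months",
            "replicate",
        ],
    )
    return validate_storage_table(df)


def write_json_report(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"cannot serialise {type(value)}")
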