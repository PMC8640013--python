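"""Multivariate analysis of storage-quality factorial tables.

Treatments (factor combinations of harvest moisture, drying temperature,
storage temperature, package and storage time) are summarised by their
replicate means over five quality variables — moisture, electrical
conductivity, oil, acidity and crude protein.  The analysis pipeline is:

1. standardise each variable to zero mean, unit sample SD;
2. agglomerative Ward (minimum-variance) clustering on Euclidean
   distances, cut into ``k`` groups;
3. Pearson correlations between the raw quality variables within each
   group (clusters with fewer than three members yield undefined
   entries);
4. Tukey HSD compact-letter displays summarising factor effects.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._errors import ContractError, SchemaError

__all__ = [
    "FACTOR_COLUMNS",
    "QUALITY_VARIABLES",
    "ClusterResult",
    "validate_storage_table",
    "treatment_means",
    "standardize",
    "ward_cluster",
    "cluster_correlations",
    "tukey_letters",
]

FACTOR_COLUMNS = (
    "harvest_moisture_pct",
    "drying_temp",
    "storage_temp_C",
    "package",
    "time_months",
)
QUALITY_VARIABLES = ("moisture_pct", "ec", "oil_pct", "acidity_ml", "protein_pct")

_FACTOR_LEVELS = {
    "harvest_moisture_pct": {18, 23},
    "drying_temp": {"80", "100", "120", "mixed"},
    "storage_temp_C": {15, 23, 30},
    "package": {"P", "PL"},
    "time_months": {0, 4, 8},
}


@dataclass
class ClusterResult:
    """Ward clustering outcome over treatment rows."""

    treatment_ids: list[str]
    labels: np.ndarray  # 1..k per treatment
    merge_heights: np.ndarray
    k: int
    linkage_matrix: np.ndarray
    group_correlations: dict[int, pd.DataFrame] | None = None


def validate_storage_table(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a storage-quality table, returning a typed copy."""
    required = list(FACTOR_COLUMNS) + ["replicate"] + list(QUALITY_VARIABLES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"storage table is missing column(s): {missing}")
    out = df.copy()
    out["drying_temp"] = out["drying_temp"].astype(str)
    out["package"] = out["package"].astype(str)
    for col, levels in _FACTOR_LEVELS.items():
        bad = set(out[col].unique()) - levels
        if bad:
            raise SchemaError(f"column {col!r} has unknown level(s): {sorted(bad)}")
    for col in QUALITY_VARIABLES:
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise SchemaError(f"column {col!r} must be positive and numeric")
        out[col] = vals
    return out


def treatment_means(
    df: pd.DataFrame, variables: Sequence[str] = QUALITY_VARIABLES
) -> pd.DataFrame:
    """Mean of each quality variable per factor combination.

    Returns one row per treatment, indexed by a readable treatment id
    like ``"23/80/15/PL/m8"``.
    """
    df = validate_storage_table(df)
    grouped = df.groupby(list(FACTOR_COLUMNS), sort=True)[list(variables)].mean()
    ids = [
        f"{h}/{d}/{s}/{p}/m{t}" for h, d, s, p, t in grouped.index
    ]
    out = grouped.reset_index(drop=True)
    out.index = pd.Index(ids, name="treatment")
    return out


def standardize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Column-wise standardisation to mean 0 and sample SD 1 (ddof=1)."""
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ContractError("need a 2-D matrix with >= 2 rows")
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        if isinstance(matrix, pd.DataFrame):
            bad = list(matrix.columns[np.flatnonzero(sd == 0)])
        else:
            bad = list(np.flatnonzero(sd == 0))
        raise ContractError(f"constant column(s) cannot be standardised: {bad}")
    z = (values - values.mean(axis=0)) / sd
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z


def ward_cluster(z_matrix: pd.DataFrame | np.ndarray, k: int) -> ClusterResult:
    """Agglomerative Ward clustering on Euclidean distances, cut at ``k`` groups.

    Uses the squared-Euclidean minimum-variance update (the "Ward.D2"
    dialect); merge heights are non-decreasing and the assignment is
    deterministic for a given input.
    """
    values = np.asarray(z_matrix, dtype=float)
    if values.ndim != 2:
        raise ContractError("need a 2-D matrix")
    n = values.shape[0]
    if not (1 <= k <= n):
        raise ContractError(f"k={k} must lie in 1..{n} (rows)")
    if isinstance(z_matrix, pd.DataFrame):
        ids = [str(i) for i in z_matrix.index]
    else:
        ids = [str(i) for i in range(n)]
    lm = linkage(values, method="ward", metric="euclidean")
    labels = fcluster(lm, t=k, criterion="maxclust")
    return ClusterResult(
        treatment_ids=ids,
        labels=np.asarray(labels, dtype=int),
        merge_heights=lm[:, 2].copy(),
        k=int(k),
        linkage_matrix=lm,
    )


def cluster_correlations(
    matrix: pd.DataFrame, labels: Sequence[int], min_size: int = 3
) -> dict[int, pd.DataFrame]:
    """Per-cluster Pearson correlation matrices over the raw variables.

    Clusters with fewer than ``min_size`` members, and variables that
    are constant within a cluster, yield NaN (undefined) entries; the
    diagonal is always 1.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(matrix):
        raise ContractError("labels length must match matrix rows")
    out: dict[int, pd.DataFrame] = {}
    cols = matrix.columns
    for lab in np.unique(labels):
        sub = matrix.iloc[labels == lab]
        if len(sub) < min_size:
            corr = pd.DataFrame(np.nan, index=cols, columns=cols)
            np.fill_diagonal(corr.values, 1.0)
        else:
            corr = sub.corr(method="pearson")
            np.fill_diagonal(corr.values, 1.0)
        out[int(lab)] = corr
    return out


# ---------------------------------------------------------------------------
# Tukey compact letter display

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def tukey_letters(
    df: pd.DataFrame,
    response: str,
    factor: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD compact-letter display.

    Returns a table with one row per factor level (sorted by descending
    mean) and a ``letters`` column; levels sharing a letter do not
    differ at ``alpha``.  Requires >= 2 levels with >= 2 replicates each.
    """
    if response not in df.columns or factor not in df.columns:
        raise SchemaError(f"missing column {response!r} or {factor!r}")
    groups = df.groupby(factor)[response]
    sizes = groups.size()
    if len(sizes) < 2:
        raise ContractError("need >= 2 factor levels")
    if (sizes < 2).any():
        raise ContractError("every factor level needs >= 2 replicates")

    means = groups.mean().sort_values(ascending=False)
    levels = list(means.index)

    pooled_var = groups.apply(lambda g: g.var(ddof=1)).fillna(0.0)
    if np.allclose(pooled_var, 0) and np.allclose(means, means.iloc[0]):
        letters = {lev: "a" for lev in levels}
    else:
        res = pairwise_tukeyhsd(
            endog=df[response].to_numpy(dtype=float),
            groups=df[factor].astype(str).to_numpy(),
            alpha=alpha,
        )
        tbl = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        different = set()
        for _, row in tbl.iterrows():
            if bool(row["reject"]):
                different.add(frozenset((str(row["group1"]), str(row["group2"]))))
        letters = _compact_letter_display([str(l) for l in levels], different)
        letters = {lev: letters[str(lev)] for lev in levels}

    out = pd.DataFrame(
        {
            factor: levels,
            "mean": [means[lev] for lev in levels],
            "n": [sizes[lev] for lev in levels],
            "letters": [letters[lev] for lev in levels],
        }
    )
    return out


def _compact_letter_display(
    ordered_levels: list[str], different: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Starts from one letter covering all levels, splits it for every
    significantly different pair, absorbs redundant subsets, then maps
    letter groups to 'a', 'b', ... in mean order.
    """
    groups: list[set[str]] = [set(ordered_levels)]
    for pair in different:
        a, b = tuple(pair)
        for g in list(groups):
            if a in g and b in g:
                groups.remove(g)
                g1, g2 = g - {a}, g - {b}
                for cand in (g1, g2):
                    if cand and not any(cand <= other for other in groups):
                        groups.append(cand)
        groups = [g for g in groups if not any(g < other for other in groups)]
    # order letter groups by the best-ranked level they contain
    rank = {lev: i for i, lev in enumerate(ordered_levels)}
    groups.sort(key=lambda g: min(rank[lev] for lev in g))
    out: dict[str, str] = {lev: "" for lev in ordered_levels}
    for i, g in enumerate(groups):
        for lev in g:
            out[lev] += _LETTERS[i % len(_LETTERS)]
    return {lev: "".join(sorted(s)) for lev, s in out.items()}
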