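"""B-/T-cell receptor repertoire statistics.

Operates on long-format repertoire tables (one row per cell: cluster,
clonotype id, isotype, somatic-hypermutation frequency). Provides SHM
binning (none / low / high at the 0.02 boundary), isotype composition,
normalised Shannon clonal diversity (1 - expansion), the clone-size-weighted
pairwise transition index, and top-k clonotype-sharing fractions against a
reference cluster.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "bin_shm",
    "isotype_composition",
    "clonal_diversity",
    "transition_index",
    "top_clonotype_sharing",
]


def bin_shm(freq: float) -> str:
    """SHM category: 0 -> "none", (0, 0.02] -> "low", > 0.02 -> "high"."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError("SHM frequency must be in [0, 1]")
    if freq == 0.0:
        return "none"
    return "low" if freq <= 0.02 else "high"


def isotype_composition(table: pd.DataFrame,
                        group_by: str = "cluster",
                        isotype_col: str = "isotype") -> pd.DataFrame:
    """Per-group isotype fractions (rows sum to 1; absent isotypes are 0)."""
    if isotype_col not in table.columns:
        raise ValueError(f"missing column {isotype_col!r}")
    nonempty = table.dropna(subset=[isotype_col])
    dropped = set(table[group_by]) - set(nonempty[group_by])
    if dropped:
        warnings.warn(f"groups with no isotype data excluded: "
                      f"{sorted(map(str, dropped))}", stacklevel=2)
    frac = (nonempty.groupby(group_by)[isotype_col]
            .value_counts(normalize=True).unstack(fill_value=0.0))
    return frac


def _clone_sizes(table: pd.DataFrame, cluster: str) -> np.ndarray:
    sub = table[table["cluster"] == cluster]
    if sub.empty:
        raise ValueError(f"cluster {cluster!r} is empty")
    return sub["clonotype_id"].value_counts().to_numpy(dtype=float)


def clonal_diversity(table: pd.DataFrame, cluster: str) -> float:
    """Normalised Shannon diversity of clone sizes, in [0, 1].

    With clone-size proportions p_i over k clonotypes the diversity is
    H / ln k, H = -sum p_i ln p_i; equivalently 1 - expansion with expansion
    = 1 - H/ln k. A single clonotype gives 0 (fully expanded), all-singleton
    clones give 1.
    """
    sizes = _clone_sizes(table, cluster)
    k = len(sizes)
    if k == 1:
        return 0.0
    p = sizes / sizes.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(k)


def transition_index(table: pd.DataFrame,
                     cluster_a: str, cluster_b: str) -> float:
    """Clone-size-weighted cell-linking index between two clusters, in [0,1].

    Restricted to cells of the two clusters: each clonotype with split
    (n_A, n_B) contributes its split entropy normalised by ln 2, weighted by
    its share of the cells. 0 when no clonotype spans both clusters; 1 when
    every clonotype splits 50/50.
    """
    sub = table[table["cluster"].isin([cluster_a, cluster_b])]
    if (sub["cluster"] == cluster_a).sum() == 0 \
            or (sub["cluster"] == cluster_b).sum() == 0:
        raise ValueError("both clusters must be non-empty")
    counts = (sub.groupby(["clonotype_id", "cluster"]).size()
              .unstack(fill_value=0)
              .reindex(columns=[cluster_a, cluster_b], fill_value=0))
    n = counts.to_numpy(dtype=float)
    tot = n.sum(axis=1)
    p = n / tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1) / np.log(2)
    return float((tot / tot.sum() * h).sum())


def top_clonotype_sharing(table: pd.DataFrame, reference: str,
                          k: int = 10) -> pd.Series:
    """Fraction of each cluster's cells carrying one of the reference
    cluster's top-k clonotypes.

    Top-k is by within-reference cell count, ties broken lexicographically by
    clonotype id. The reference's own entry is the fraction of its cells in
    its top-k clonotypes.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ref = table[table["cluster"] == reference]
    if ref.empty:
        raise ValueError(f"reference cluster {reference!r} is empty")
    counts = ref["clonotype_id"].value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], str(c)))
    top = set(order[:k])
    frac = (table.assign(_hit=table["clonotype_id"].isin(top))
            .groupby("cluster")["_hit"].mean())
    frac.name = f"sharing_top{k}_{reference}"
    return frac
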