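"""QC, normalisation and gene-set scoring.

Implements the expression-side primitives: hard QC thresholds
(>=1001 UMIs, >=501 detected genes, <=25% mitochondrial UMIs),
log-normalisation, control-bin module scores, single-sample GSEA
(ssGSEA) enrichment, Wilcoxon/Bonferroni marker ranking with a log2
fold-change floor, top-k DEG signatures, and the Livak 2^-ddCt relative
EBV-DNA load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats

from .signatures import SignatureSet

__all__ = [
    "QCThresholds",
    "qc_filter",
    "log_normalize",
    "module_score",
    "ssgsea_score",
    "rank_markers",
    "top_k_signature",
    "ddct_ebv_load",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell/spot retention thresholds (inclusive keep-side boundaries)."""

    min_umis: int = 1001
    min_genes: int = 501
    max_mito_fraction: float = 0.25

    def __post_init__(self) -> None:
        if (self.min_umis <= 0 or self.min_genes <= 0
                or self.max_mito_fraction <= 0):
            raise ValueError("QC thresholds must be positive")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def qc_filter(adata: ad.AnnData,
              mito_prefixes: Sequence[str] = ("MT-",),
              thresholds: QCThresholds = QCThresholds(),
              ) -> tuple[ad.AnnData, dict[str, int]]:
    """Drop low-quality units from a count matrix.

    A unit is kept iff total UMIs >= `min_umis`, detected genes >=
    `min_genes`, and mitochondrial UMI fraction <= `max_mito_fraction`
    (strictly "over" the threshold is removed). Mitochondrial genes are
    identified by name prefix. Returns the filtered copy and per-rule removal
    counts (a unit may count under several rules).
    """
    X = _dense(adata.X)
    if (X < 0).any():
        raise ValueError("qc_filter expects a non-negative count matrix")
    total = X.sum(axis=1)
    n_genes = (X > 0).sum(axis=1)
    mito_mask = np.array(
        [any(g.upper().startswith(p.upper()) for p in mito_prefixes)
         for g in adata.var_names])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito_mask].sum(axis=1)
                             / np.maximum(total, 1), 0.0)

    low_umi = total < thresholds.min_umis
    low_genes = n_genes < thresholds.min_genes
    high_mito = mito_frac > thresholds.max_mito_fraction
    keep = ~(low_umi | low_genes | high_mito)
    report = {
        "low_umis": int(low_umi.sum()),
        "low_genes": int(low_genes.sum()),
        "high_mito": int(high_mito.sum()),
        "kept": int(keep.sum()),
        "removed": int((~keep).sum()),
    }
    if keep.sum() == 0 and adata.n_obs > 0:
        warnings.warn("qc_filter removed every unit", stacklevel=2)
    return adata[keep].copy(), report


def log_normalize(adata: ad.AnnData,
                  scale_factor: float = 10_000.0) -> ad.AnnData:
    """Depth-normalise to `scale_factor` counts per unit and log1p.

    value = ln(1 + count * scale_factor / unit_total). Units with zero total
    stay all-zero (with a warning).
    """
    if scale_factor <= 0:
        raise ValueError("scale factor must be > 0")
    X = _dense(adata.X)
    if (X < 0).any():
        raise ValueError("log_normalize expects non-negative counts")
    out = adata.copy()
    totals = X.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} unit(s) have zero counts; "
                      "their normalised rows are all zero", stacklevel=2)
    out.X = X.astype(float)
    sc.pp.normalize_total(out, target_sum=scale_factor)
    sc.pp.log1p(out)
    out.uns["layer"] = "lognorm"
    return out


# ---------------------------------------------------------------------------
# control-bin module score
# ---------------------------------------------------------------------------

def module_score(expr: ad.AnnData | pd.DataFrame,
                 signature: SignatureSet | Sequence[str],
                 n_bins: int = 24,
                 n_ctrl: int = 100,
                 seed: int = 0) -> pd.Series:
    """Expression-bin-controlled gene-module score per unit.

    All genes are ranked by their dataset-average expression and cut into
    `n_bins` equal-size bins. For every signature gene, `n_ctrl` control
    genes are sampled without replacement from its bin (signature genes
    excluded); the score of a unit is the mean expression of the signature
    genes minus the mean expression of the pooled control draws. Scores are
    computed on log-normalised values and are ~0 for a signature that behaves
    like its expression-matched background.
    """
    if isinstance(expr, ad.AnnData):
        df = pd.DataFrame(_dense(expr.X), index=expr.obs_names,
                          columns=expr.var_names)
    else:
        df = expr
    genes = list(signature.genes if isinstance(signature, SignatureSet)
                 else signature)
    present = [g for g in genes if g in df.columns]
    if not present:
        raise ValueError("no signature gene is present in the matrix")
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")

    rng = np.random.default_rng(seed)
    avg = df.mean(axis=0)
    # ties broken by average rank, then a stable order for binning
    order = avg.rank(method="average").sort_values(kind="stable").index
    bins = np.array_split(np.arange(len(order)), n_bins)
    bin_of = {}
    for b, idx in enumerate(bins):
        for gi in idx:
            bin_of[order[gi]] = b
    members: dict[int, list[str]] = {}
    sig_set = set(present)
    for g in order:
        members.setdefault(bin_of[g], []).append(g)

    controls: list[str] = []
    for g in present:
        b = bin_of[g]
        pool = [c for c in members[b] if c not in sig_set]
        width = 1
        while not pool and width < n_bins:
            # signature genes exhausted the bin: widen to neighbouring bins
            for nb in (b - width, b + width):
                if nb in members:
                    pool += [c for c in members[nb] if c not in sig_set]
            width += 1
        if len(pool) >= n_ctrl:
            pick = rng.choice(len(pool), size=n_ctrl, replace=False)
        else:
            warnings.warn(
                f"bin of gene {g!r} has only {len(pool)} control candidates; "
                "sampling with replacement", stacklevel=2)
            if not pool:
                continue
            pick = rng.choice(len(pool), size=n_ctrl, replace=True)
        controls.extend(pool[i] for i in pick)
    if not controls:
        raise ValueError("no control genes could be sampled")
    score = df[present].mean(axis=1) - df[controls].mean(axis=1)
    score.name = (signature.name if isinstance(signature, SignatureSet)
                  else "module_score")
    return score


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(expr: pd.DataFrame | ad.AnnData,
                 signatures: Mapping[str, SignatureSet] | SignatureSet,
                 alpha: float = 0.25,
                 rescale: bool = False) -> pd.DataFrame:
    """Single-sample GSEA enrichment (samples x signatures).

    Per sample, genes are ranked by expression (average ranks on ties, then a
    deterministic ordering by rank and gene position). The enrichment score is
    the sum over the ranked list of the difference between the weighted
    in-set ECDF — weights ``rank^alpha`` — and the uniform out-of-set ECDF.
    With ``rescale=True`` scores are min-max rescaled across samples per
    signature.
    """
    if isinstance(expr, ad.AnnData):
        df = pd.DataFrame(_dense(expr.X), index=expr.obs_names,
                          columns=expr.var_names)
    else:
        df = expr
    if isinstance(signatures, SignatureSet):
        signatures = {signatures.name: signatures}
    n_genes = df.shape[1]
    gene_pos = {g: i for i, g in enumerate(df.columns)}

    out = pd.DataFrame(index=df.index, columns=list(signatures), dtype=float)
    for name, sig in signatures.items():
        in_set = np.zeros(n_genes, dtype=bool)
        hit = [gene_pos[g] for g in sig.genes if g in gene_pos]
        if not hit:
            raise ValueError(f"signature {name!r} shares no gene with the "
                             "matrix")
        in_set[hit] = True
        if in_set.all():
            raise ValueError(f"signature {name!r} covers every gene; the "
                             "out-of-set ECDF is undefined")
        for si, (_, row) in enumerate(df.iterrows()):
            vals = row.to_numpy(dtype=float)
            ranks = stats.rankdata(vals, method="average")
            # descending by rank; ties resolved by gene position (stable)
            order = np.lexsort((np.arange(n_genes), -ranks))
            inset_o = in_set[order]
            w = ranks[order] ** alpha
            w_in = np.where(inset_o, w, 0.0)
            denom_in = w_in.sum()
            p_in = np.cumsum(w_in) / denom_in
            p_out = np.cumsum(~inset_o) / (n_genes - in_set.sum())
            out.iloc[si, out.columns.get_loc(name)] = float(
                np.sum(p_in - p_out))
    if rescale:
        rng_ = out.max(axis=0) - out.min(axis=0)
        rng_ = rng_.replace(0, 1.0)
        out = (out - out.min(axis=0)) / rng_
    return out


# ---------------------------------------------------------------------------
# marker ranking
# ---------------------------------------------------------------------------

def rank_markers(expr: ad.AnnData | pd.DataFrame,
                 labels: pd.Series | Sequence[str] | None = None,
                 min_log2fc: float = 0.25,
                 alpha: float = 0.05,
                 correction: str = "bonferroni") -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    For every gene and cluster, a two-sided Wilcoxon rank-sum test contrasts
    the cluster's units with all others; p-values are Bonferroni-adjusted
    over genes (Benjamini-Hochberg available via ``correction="bh"``). Genes
    pass with adjusted p < `alpha` and log2 fold-change >= `min_log2fc`,
    where log2FC is the difference of mean log-normalised expression divided
    by ln 2. The table is sorted by cluster then descending fold-change.
    Clusters with fewer than 3 units are skipped with a warning.
    """
    if isinstance(expr, ad.AnnData):
        df = pd.DataFrame(_dense(expr.X), index=expr.obs_names,
                          columns=expr.var_names)
        if labels is None and "cluster" in expr.obs:
            labels = expr.obs["cluster"]
    else:
        df = expr
    if labels is None:
        raise ValueError("cluster labels are required")
    lab = np.asarray(labels)
    if len(set(lab)) < 2:
        raise ValueError("need at least 2 distinct cluster labels")
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")

    X = df.to_numpy(dtype=float)
    n_genes = X.shape[1]
    frames = []
    for cl in pd.unique(lab):
        mask = lab == cl
        if mask.sum() < 3:
            warnings.warn(f"cluster {cl!r} has fewer than 3 units; skipped",
                          stacklevel=2)
            continue
        a, b = X[mask], X[~mask]
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                 method="asymptotic")
        pvals = np.asarray(res.pvalue)
        if correction == "bonferroni":
            padj = np.minimum(pvals * n_genes, 1.0)
        else:
            padj = stats.false_discovery_control(pvals, method="bh")
        log2fc = (a.mean(axis=0) - b.mean(axis=0)) / np.log(2)
        keep = (padj < alpha) & (log2fc >= min_log2fc)
        frames.append(pd.DataFrame({
            "cluster": cl,
            "gene": df.columns[keep],
            "log2fc": log2fc[keep],
            "pval": pvals[keep],
            "padj": padj[keep],
        }))
    if not frames:
        return pd.DataFrame(columns=["cluster", "gene", "log2fc",
                                     "pval", "padj"])
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["cluster", "log2fc"],
                             ascending=[True, False],
                             kind="stable").reset_index(drop=True)


def top_k_signature(markers: pd.DataFrame,
                    k: int = 100) -> dict[str, SignatureSet]:
    """Top-k marker genes per cluster, in the marker table's sort order."""
    if markers.empty:
        raise ValueError("marker table is empty")
    if k <= 0:
        raise ValueError("k must be positive")
    out: dict[str, SignatureSet] = {}
    for cl, grp in markers.groupby("cluster", sort=False):
        genes = tuple(grp["gene"].head(k))
        if len(genes) < k:
            warnings.warn(f"cluster {cl!r} has only {len(genes)} markers "
                          f"(< {k}); returning all", stacklevel=2)
        out[str(cl)] = SignatureSet(name=str(cl), genes=genes, role="DEG")
    return out


# ---------------------------------------------------------------------------
# EBV DNA load (Livak 2^-ddCt)
# ---------------------------------------------------------------------------

def ddct_ebv_load(ct: pd.DataFrame,
                  calibrator: tuple[float, float]) -> pd.DataFrame:
    """Relative EBV DNA copy number by the Livak 2^-ddCt method.

    `ct` needs columns ``ct_target`` and ``ct_ref`` (viral marker and
    internal reference Ct per sample); `calibrator` is the positive-control
    (Ct_target, Ct_ref) pair. Samples are split into high/low EBV-load groups
    at the cohort mean of the relative values.
    """
    if calibrator is None or len(calibrator) != 2:
        raise ValueError("calibrator (Ct_target, Ct_ref) is required")
    cal_t, cal_r = map(float, calibrator)
    for col in ("ct_target", "ct_ref"):
        if col not in ct.columns:
            raise ValueError(f"missing column {col!r}")
    vals = ct["ct_target"].to_numpy(float), ct["ct_ref"].to_numpy(float)
    if not (np.isfinite(vals[0]).all() and np.isfinite(vals[1]).all()
            and np.isfinite([cal_t, cal_r]).all()):
        raise ValueError("all Ct values must be finite")
    ddct = (vals[0] - vals[1]) - (cal_t - cal_r)
    rel = np.power(2.0, -ddct)
    out = ct.copy()
    out["rel_copy_number"] = rel
    out["group"] = np.where(rel > rel.mean(), "high", "low")
    return out
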