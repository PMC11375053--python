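"""Spatial compartment calling and TCA stratification.

Spots are classified as tumour-cell aggregate (TCA), tertiary lymphoid
structure (TLS) or stroma from z-standardised malignant / B / T signature
scores; contiguous TCA spots form components, which are stratified by
quartiles of an EBV signature (>Q3 high, <Q1 low, else mid; component label
by spot majority vote) and by plasma-cell co-occurrence (wP/woP: any spot of
the component or its one-pitch halo above the sample's plasma-score
quantile). Apoptosis scores are then compared across the resulting classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "SpotGrid",
    "bin_stereo_spots",
    "call_regions",
    "find_tca_components",
    "stratify_ebv",
    "classify_plasma_cooccurrence",
    "compare_apoptosis",
    "normalized_connection",
    "infiltration_bin",
]

#: raw Stereo-seq capture-spot pitch, µm
_STEREO_RAW_PITCH = 0.5


@dataclass
class SpotGrid:
    """Spot identifiers with planar µm coordinates and platform geometry."""

    coords: pd.DataFrame          # index: spot id; columns x, y (µm)
    platform: str = "visium-hex"  # "visium-hex" | "stereo-bin"
    pitch: float = 100.0

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not self.coords.index.is_unique:
            raise ValueError("spot ids must be unique")
        if not np.isfinite(self.coords[["x", "y"]].to_numpy()).all():
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "SpotGrid":
        xy = pd.DataFrame(adata.obsm["spatial"], index=adata.obs_names,
                          columns=["x", "y"])
        return cls(coords=xy, platform=adata.uns.get("platform", "visium-hex"),
                   pitch=float(adata.uns.get("pitch", 100.0)))


def bin_stereo_spots(counts: pd.DataFrame, coords: pd.DataFrame,
                     bin_width: int = 100,
                     already_binned: bool = False,
                     ) -> tuple[pd.DataFrame, SpotGrid]:
    """Aggregate raw Stereo-seq spots (0.5 µm pitch) into square bins.

    ``bin_width`` counts raw spots per side; the default 100 gives the
    bin100 unit of ~49.72 µm. Counts are summed within each window; the bin
    coordinate is the window centre. Partial edge windows are kept and
    flagged in the returned grid's ``coords["partial"]``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if already_binned:
        raise ValueError("input is flagged as already binned")
    ix = np.floor(coords["x"].to_numpy() / _STEREO_RAW_PITCH + 0.5).astype(int)
    iy = np.floor(coords["y"].to_numpy() / _STEREO_RAW_PITCH + 0.5).astype(int)
    bx, by = ix // bin_width, iy // bin_width
    key = pd.Series([f"bin_{a}_{b}" for a, b in zip(bx, by)],
                    index=counts.index)
    binned = counts.groupby(key.to_numpy()).sum()

    pitch = bin_width * _STEREO_RAW_PITCH * 0.9944  # 100 spots ~ 49.72 µm
    meta = pd.DataFrame({"bx": bx, "by": by}, index=counts.index) \
        .groupby(key.to_numpy()).first()
    full = pd.DataFrame({"bx": bx, "by": by}).value_counts()
    centers = pd.DataFrame({
        "x": (meta["bx"] + 0.5) * pitch,
        "y": (meta["by"] + 0.5) * pitch,
        "partial": [full[(a, b)] < bin_width ** 2
                    for a, b in zip(meta["bx"], meta["by"])],
    }, index=binned.index)
    grid = SpotGrid(coords=centers, platform="stereo-bin", pitch=pitch)
    return binned, grid


def call_regions(scores: pd.DataFrame, z_threshold: float = 0.5) -> pd.Series:
    """Per-spot region label from malignant / B / T signature scores.

    Scores are z-standardised across spots. A spot is TCA when the malignant
    z-score exceeds the threshold and is the (tie-inclusive) maximum; TLS
    when the best lymphocyte z-score (B or T) exceeds the threshold and
    strictly beats the malignant one; otherwise stroma. Ties favour
    TCA > TLS > stroma.
    """
    for col in ("malignant", "B", "T"):
        if col not in scores.columns:
            raise ValueError(f"missing score column {col!r}")
        if np.isclose(scores[col].std(ddof=0), 0.0):
            raise ValueError(f"score {col!r} is constant; z undefined")
    z = (scores - scores.mean()) / scores.std(ddof=0)
    zm = z["malignant"].to_numpy()
    zl = np.maximum(z["B"].to_numpy(), z["T"].to_numpy())
    region = np.full(len(scores), "stroma", dtype=object)
    region[(zl > z_threshold) & (zl > zm)] = "TLS"
    region[(zm > z_threshold) & (zm >= zl)] = "TCA"
    return pd.Series(region, index=scores.index, name="region")


def find_tca_components(regions: pd.Series, grid: SpotGrid,
                        radius_factor: float = 1.2) -> pd.Series:
    """Connected components of TCA spots.

    Two TCA spots are adjacent when their centre distance is at most
    ``radius_factor * pitch`` (default 1.2: nearest neighbours on both the
    hexagonal and the square grid). Components are numbered deterministically
    by their smallest spot id; non-TCA spots get -1.
    """
    tca_ids = regions.index[regions == "TCA"]
    comp = pd.Series(-1, index=regions.index, name="component")
    if len(tca_ids) == 0:
        return comp
    xy = grid.coords.loc[tca_ids, ["x", "y"]].to_numpy()
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius_factor * grid.pitch,
                             output_type="ndarray")
    n = len(tca_ids)
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, raw = connected_components(adj, directed=False)
    # renumber by the smallest spot id inside each raw component
    order = {}
    for rc in pd.unique(raw):
        order[rc] = min(tca_ids[raw == rc])
    relabel = {rc: i for i, rc in enumerate(
        sorted(order, key=lambda rc: order[rc]))}
    comp.loc[tca_ids] = [relabel[rc] for rc in raw]
    return comp


def stratify_ebv(components: pd.Series,
                 ebv_score: pd.Series) -> tuple[pd.Series, dict[int, str]]:
    """EBV class per TCA spot and per component.

    Spot-level quartiles of the EBV signature over all TCA spots: strictly
    above Q3 is high, strictly below Q1 low, else mid. A component's class
    is the majority vote of its spots; ties resolve to mid. Fewer than 4 TCA
    spots: everything mid, with a warning.
    """
    tca = components.index[components >= 0]
    spot_class = pd.Series("none", index=components.index, name="ebv_class",
                           dtype=object)
    if len(tca) < 4:
        warnings.warn("fewer than 4 TCA spots; all components classed mid",
                      stacklevel=2)
        spot_class.loc[tca] = "mid"
        return spot_class, {int(c): "mid" for c in pd.unique(components[tca])}
    s = ebv_score.reindex(tca).to_numpy(dtype=float)
    q1, q3 = np.quantile(s, [0.25, 0.75])
    cls = np.where(s > q3, "high", np.where(s < q1, "low", "mid"))
    spot_class.loc[tca] = cls

    comp_class: dict[int, str] = {}
    for c in pd.unique(components[tca]):
        votes = spot_class[tca][components[tca] == c].value_counts()
        top = votes[votes == votes.max()].index
        comp_class[int(c)] = top[0] if len(top) == 1 else "mid"
    return spot_class, comp_class


def classify_plasma_cooccurrence(components: pd.Series,
                                 plasma_score: pd.Series,
                                 grid: SpotGrid,
                                 occupancy_quantile: float = 0.75,
                                 ) -> dict[int, str]:
    """wP/woP flag per TCA component.

    A component is "wP" (with plasma cells) iff at least one of its spots —
    or any spot within one pitch of one of its spots — has a plasma-signature
    score strictly above the sample-wide `occupancy_quantile` of that
    score; otherwise "woP".
    """
    if not 0.0 <= occupancy_quantile <= 1.0:
        raise ValueError("occupancy quantile must be in [0, 1]")
    thr = float(np.quantile(plasma_score.to_numpy(dtype=float),
                            occupancy_quantile))
    hot = plasma_score.index[plasma_score > thr] if occupancy_quantile > 0 \
        else plasma_score.index
    hot_xy = grid.coords.loc[hot, ["x", "y"]].to_numpy()
    tree = cKDTree(hot_xy) if len(hot_xy) else None

    out: dict[int, str] = {}
    for c in pd.unique(components[components >= 0]):
        spots = components.index[components == c]
        xy = grid.coords.loc[spots, ["x", "y"]].to_numpy()
        wp = False
        if tree is not None:
            d, _ = tree.query(xy, k=1)
            wp = bool((d <= grid.pitch * 1.05).any())
        out[int(c)] = "wP" if wp else "woP"
    return out


def compare_apoptosis(spot_class: pd.Series,
                      apoptosis: pd.Series,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Summaries and Welch t-tests of apoptosis scores across TCA classes.

    `spot_class` gives a class label per spot (e.g. "high-wP"); spots
    labelled "none" are ignored, classes with fewer than 2 spots are excluded
    with a warning. Returns (per-class summary, pairwise two-sided Welch
    t-test table, name of the class with the highest mean).
    """
    mask = spot_class != "none"
    df = pd.DataFrame({"cls": spot_class[mask],
                       "score": apoptosis.reindex(spot_class.index[mask])})
    sizes = df["cls"].value_counts()
    small = sizes.index[sizes < 2]
    if len(small):
        warnings.warn(f"classes with <2 spots excluded: {list(small)}",
                      stacklevel=2)
        df = df[~df["cls"].isin(small)]
    classes = sorted(df["cls"].unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes with >= 2 spots")

    summary = df.groupby("cls")["score"].agg(
        n="size", mean="mean", median="median",
        iqr=lambda s: s.quantile(0.75) - s.quantile(0.25)).reset_index()
    rows = []
    for a, b in itertools.combinations(classes, 2):
        t, p = stats.ttest_ind(df.loc[df["cls"] == a, "score"],
                               df.loc[df["cls"] == b, "score"],
                               equal_var=False)
        rows.append({"class_a": a, "class_b": b, "t": t, "p": p})
    highest = summary.loc[summary["mean"].idxmax(), "cls"]
    return summary, pd.DataFrame(rows), str(highest)


def normalized_connection(value: float, n_a: int, n_b: int) -> float:
    """Cell-number-normalised interaction: value / (n_a * n_b)."""
    if n_a < 1 or n_b < 1:
        raise ValueError("cluster cell counts must be >= 1")
    return float(value) / (n_a * n_b)


def infiltration_bin(fraction: float) -> int:
    """Immune-infiltration score bin of the infiltrated tumour-area fraction.

    Bins 1..4 cover (0, 0.25], (0.25, 0.50], (0.50, 0.75], (0.75, 1.0];
    a fraction of exactly 0 maps to bin 1.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0.0:
        return 1
    return max(1, int(np.ceil(fraction / 0.25 - 1e-12)))
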