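"""Distance statistics between phenotyped cell points from multiplex imaging.

The core quantity is the number of target cells (e.g. CASP3+PanCK+ apoptotic
tumour cells) lying within a radius — 20 µm by default — of any anchor cell
(e.g. IgG+ plasma cells), with the boundary counted inclusively, plus the
per-target nearest-anchor distance distribution and its closed-form
expectation under complete spatial randomness (CSR).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "count_within_radius",
    "count_within_radius_by_image",
    "distance_histogram",
    "csr_expected_count",
]


def count_within_radius(anchors: pd.DataFrame, targets: pd.DataFrame,
                        radius: float = 20.0) -> tuple[int, pd.Series]:
    """Targets within `radius` µm of any anchor (closed boundary).

    Returns the count and each target's minimum Euclidean distance to the
    anchor set (exact; KD-tree indexed). With no anchors the count is 0 and
    distances are +inf, with a warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(targets) == 0:
        return 0, pd.Series(dtype=float, name="min_dist")
    if len(anchors) == 0:
        warnings.warn("no anchor cells; count is 0", stacklevel=2)
        return 0, pd.Series(np.inf, index=targets.index, name="min_dist")
    tree = cKDTree(anchors[["x", "y"]].to_numpy(dtype=float))
    d, _ = tree.query(targets[["x", "y"]].to_numpy(dtype=float), k=1)
    dist = pd.Series(d, index=targets.index, name="min_dist")
    return int((d <= radius).sum()), dist


def count_within_radius_by_image(cells: pd.DataFrame,
                                 anchor_flag: str, target_flag: str,
                                 radius: float = 20.0,
                                 image_col: str = "image_id") -> pd.DataFrame:
    """Per-image within-radius counts; images analysed independently."""
    rows = []
    for img, grp in cells.groupby(image_col):
        n, _ = count_within_radius(grp[grp[anchor_flag]],
                                   grp[grp[target_flag]], radius)
        rows.append({image_col: img, "n_anchors": int(grp[anchor_flag].sum()),
                     "n_targets": int(grp[target_flag].sum()),
                     "count_within": n})
    return pd.DataFrame(rows)


def distance_histogram(distances: pd.Series | np.ndarray,
                       bin_edges: np.ndarray) -> pd.Series:
    """Right-closed binned counts of nearest-anchor distances.

    Bin i covers (edge_i, edge_{i+1}]; the first bin additionally includes
    its left edge so counts conserve the number of targets with a finite
    distance inside the edge range.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    labels = [f"({edges[i]:g}, {edges[i+1]:g}]" for i in range(len(edges) - 1)]
    if len(d) == 0:
        return pd.Series(0, index=labels, name="count")
    idx = np.searchsorted(edges, d, side="left") - 1
    idx[d == edges[0]] = 0
    counts = np.bincount(idx[(idx >= 0) & (idx < len(edges) - 1)],
                         minlength=len(edges) - 1)
    return pd.Series(counts, index=labels, name="count")


def csr_expected_count(n_anchors: int, n_targets: int,
                       radius: float, area: float) -> float:
    """Expected within-radius target count under complete spatial randomness.

    E = n_targets * (1 - (1 - pi r^2 / A)^n_anchors), ignoring edge effects.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    p = math.pi * radius ** 2 / area
    if p > 1:
        raise ValueError("pi r^2 exceeds the field area")
    return n_targets * (1.0 - (1.0 - p) ** n_anchors)
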