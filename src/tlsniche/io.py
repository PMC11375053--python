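"""Plain-text IO for the package's data products.

Expression matrices travel as MTX plus row/column TSVs (the exchange format
of the spatial platforms' pipelines); coordinates, ground truth, repertoires,
point tables and survival tables as CSV/TSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["write_expression", "read_expression",
           "write_spot_coords", "read_spot_coords"]


def write_expression(adata: ad.AnnData, outdir: str | Path,
                     prefix: str = "matrix") -> None:
    """Write units x genes counts as ``<prefix>.mtx`` + barcode/gene TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(np.asarray(adata.X))
    scipy.io.mmwrite(outdir / f"{prefix}.mtx", X)
    (outdir / f"{prefix}.barcodes.tsv").write_text(
        "\n".join(adata.obs_names) + "\n")
    (outdir / f"{prefix}.genes.tsv").write_text(
        "\n".join(adata.var_names) + "\n")
    if "spatial" in adata.obsm:
        pd.DataFrame(adata.obsm["spatial"], index=adata.obs_names,
                     columns=["x", "y"]).to_csv(outdir / f"{prefix}.coords.csv")


def read_expression(outdir: str | Path, prefix: str = "matrix") -> ad.AnnData:
    """Read a matrix written by :func:`write_expression`."""
    outdir = Path(outdir)
    X = sp.csr_matrix(scipy.io.mmread(outdir / f"{prefix}.mtx"))
    obs = (outdir / f"{prefix}.barcodes.tsv").read_text().splitlines()
    var = (outdir / f"{prefix}.genes.tsv").read_text().splitlines()
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=obs),
                       var=pd.DataFrame(index=var))
    coords = outdir / f"{prefix}.coords.csv"
    if coords.exists():
        adata.obsm["spatial"] = (pd.read_csv(coords, index_col=0)
                                 .loc[obs, ["x", "y"]].to_numpy())
    return adata


def write_spot_coords(coords: pd.DataFrame, path: str | Path) -> None:
    coords.to_csv(path)


def read_spot_coords(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
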