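"""Plain-text IO helpers: MTX counts + TSV metadata directories, regulon
GMT/JSON, edge-table TSV and GraphML graphs."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import networkx as nx
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .grn import RegulonSet
from .network import GRNGraph


def read_dataset(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(mmread(indir / "counts.mtx"))
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_adata(adata: ad.AnnData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X.tocoo() if sp.issparse(adata.X) else sp.coo_matrix(adata.X)
    mmwrite(outdir / "counts.mtx", X)
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")


def write_regulons(regulons: RegulonSet, outdir: str | Path, stem: str = "regulons") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{stem}.gmt").write_text(regulons.as_gmt())
    payload = {
        tf: {
            "targets": regulons.targets(tf),
            "mean_im": regulons.table.loc[regulons.table["tf"] == tf, "mean_im"].tolist(),
        }
        for tf in regulons.tfs()
    }
    (outdir / f"{stem}.json").write_text(json.dumps(payload, indent=1))


def write_graph(grn: GRNGraph, outdir: str | Path, stem: str = "grn") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(grn.graph, outdir / f"{stem}.graphml")
    grn.edge_table().to_csv(outdir / f"{stem}_edges.tsv", sep="\t", index=False)
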