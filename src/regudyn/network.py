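"""GRN graph construction, hub analysis and regulon dynamics across age.

A consensus edge table (or pruned regulon set) is thresholded at a top
importance-metric percentile to keep only the strongest TF->target
relationships; the surviving edges form an undirected bipartite-ish graph
on which shortest-path betweenness centrality ranks hub TFs. Age-resolved
regulon sets are compared by size, overlap (Jaccard) and by clustering the
baseline-ratio z-score profiles of regulon sizes across ordered age groups
into temporal families with fuzzy c-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from ._cmeans import fuzzy_cmeans
from .grn import ConsensusGRN, RegulonSet, regulon_size_table

__all__ = [
    "GRNGraph",
    "build_grn",
    "betweenness",
    "age_group_grns",
    "cluster_regulon_dynamics",
    "extract_subnetwork",
    "regulon_overlap",
    "RegulonDynamicsClusterer",
]

FLAT = "flat"


@dataclass
class GRNGraph:
    """Undirected TF->target graph kept at a top-IM percentile."""

    graph: nx.Graph
    im_percentile: float
    betweenness_: pd.Series | None = field(default=None, repr=False)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (d["tf"], d["target"], d["mean_im"])
            for _, _, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["tf", "target", "mean_im"])

    def tf_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "tf"]


def _edges_frame(source: pd.DataFrame | RegulonSet) -> pd.DataFrame:
    if isinstance(source, RegulonSet):
        return source.table[["tf", "target", "mean_im"]].copy()
    return source[["tf", "target", "mean_im"]].copy()


def build_grn(source: pd.DataFrame | RegulonSet, im_percentile: float = 0.85) -> GRNGraph:
    """Keep the ``ceil((1 - im_percentile) * N)`` strongest edges.

    Ties in mean IM are broken lexicographically by (tf, target), making
    the survivor set deterministic. Isolated nodes are absent by
    construction.
    """
    edges = _edges_frame(source)
    if edges.empty:
        raise ValueError("empty edge set")
    if not 0.0 <= im_percentile < 1.0:
        raise ValueError("im_percentile must lie in [0, 1)")
    # round guard: 0.15 * 100 is 15.000000000000002 in floating point
    n_keep = int(np.ceil(np.round((1.0 - im_percentile) * len(edges), 9)))
    kept = edges.sort_values(
        ["mean_im", "tf", "target"], ascending=[False, True, True], kind="mergesort"
    ).head(n_keep)
    if kept.empty:
        raise ValueError("no edges survive the percentile filter")
    G = nx.Graph()
    tf_namespace = set(edges["tf"])  # full TF namespace, not just survivors
    for _, row in kept.iterrows():
        tf, tg = row["tf"], row["target"]
        G.add_node(tf, kind="tf")
        G.add_node(tg, kind="tf" if tg in tf_namespace else "gene")
        G.add_edge(tf, tg, tf=tf, target=tg, mean_im=float(row["mean_im"]))
    return GRNGraph(graph=G, im_percentile=im_percentile)


def betweenness(grn: GRNGraph | nx.Graph, normalized: bool = True) -> pd.Series:
    """Shortest-path betweenness centrality on the undirected skeleton.

    Normalization divides by ``(n-1)(n-2)/2``; graphs with fewer than three
    nodes score zero everywhere.
    """
    G = grn.graph if isinstance(grn, GRNGraph) else grn
    if G.number_of_nodes() < 3:
        scores = pd.Series(0.0, index=list(G.nodes))
    else:
        scores = pd.Series(nx.betweenness_centrality(G, normalized=normalized))
    if isinstance(grn, GRNGraph):
        grn.betweenness_ = scores
        nx.set_node_attributes(G, scores.to_dict(), "betweenness")
    return scores


def assign_age_groups(
    ages: pd.Series,
    bins: Mapping[str, tuple[float, float]] | None = None,
) -> pd.Series:
    """Map ages in years onto labelled bins (default infant/adult/old)."""
    if bins is None:
        bins = {"infant": (0, 10), "adult": (20, 59), "old": (60.0001, np.inf)}
    out = pd.Series(pd.NA, index=ages.index, dtype=object)
    for name, (lo, hi) in bins.items():
        out[(ages >= lo) & (ages <= hi)] = name
    return out


def age_group_grns(
    adata: ad.AnnData,
    tf_list: Sequence[str],
    prior: pd.DataFrame,
    group_col: str = "age_group",
    groups: Sequence[str] | None = None,
    min_cells: int = 100,
    im_percentile: float = 0.85,
    random_state: int = 0,
    **grn_kw,
) -> dict[str, dict]:
    """Infer one consensus GRN per age group on that group's cells.

    Each group gets its own deterministic seed stream; undersized groups
    are skipped with a warning. Returns per group the fitted regulons and
    percentile-filtered graph, plus the cross-group regulon size table
    under the ``"size_table"`` key.
    """
    labels = adata.obs[group_col].astype(str)
    group_names = list(groups) if groups is not None else list(pd.unique(labels))
    out: dict[str, dict] = {}
    regulons_by_group: dict[str, RegulonSet] = {}
    for gi, g in enumerate(group_names):
        mask = (labels == g).to_numpy()
        if mask.sum() < min_cells:
            warnings.warn(f"group {g!r} has {int(mask.sum())} cells (< {min_cells}); skipped")
            continue
        sub = adata[mask].copy()
        model = ConsensusGRN(
            tf_list=tf_list, prior=prior, random_state=random_state + 1000 * gi, **grn_kw
        ).fit(sub)
        graph = (
            build_grn(model.regulons_, im_percentile)
            if len(model.regulons_.table)
            else None
        )
        out[g] = {"model": model, "regulons": model.regulons_, "graph": graph}
        regulons_by_group[g] = model.regulons_
    if regulons_by_group:
        out["size_table"] = regulon_size_table(
            regulons_by_group, groups=list(regulons_by_group)
        )
    return out


def cluster_regulon_dynamics(
    size_table: pd.DataFrame,
    k: int = 6,
    baseline: str | None = None,
    seed: int = 0,
    n_restarts: int = 100,
    fuzzifier: float = 2.0,
) -> pd.DataFrame:
    """Cluster TFs into temporal families of regulon-size change.

    Sizes are converted to ratios against the baseline (youngest) group
    with a pseudocount of 1 on both terms, z-scored per TF, and the non-flat
    rows clustered with seeded fuzzy c-means (fuzzifier 2, hard assignment
    by maximum membership). Zero-variance rows are labelled ``"flat"`` and
    excluded from clustering.
    """
    groups = list(size_table.columns)
    baseline = baseline or groups[0]
    ratios = (size_table + 1).div(size_table[baseline] + 1, axis=0)
    mu = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=0)
    flat = sd < 1e-12
    z = ratios.sub(mu, axis=0).div(sd.where(~flat, 1.0), axis=0)
    n_active = int((~flat).sum())
    if k > n_active:
        raise ValueError(f"k={k} exceeds the {n_active} non-flat TF rows")
    _, _, hard = fuzzy_cmeans(
        z[~flat].to_numpy(), k=k, m=fuzzifier, n_restarts=n_restarts, seed=seed
    )
    cluster = pd.Series(FLAT, index=size_table.index, dtype=object)
    cluster[z.index[~flat]] = [int(c) + 1 for c in hard]
    out = size_table.copy()
    out.columns = [f"size_{g}" for g in groups]
    for g in groups:
        out[f"ratio_{g}"] = ratios[g]
    for g in groups:
        out[f"z_{g}"] = z[g].where(~flat, 0.0)
    out["cluster"] = cluster
    return out


def extract_subnetwork(grn: GRNGraph, tf_set: Sequence[str]) -> GRNGraph:
    """Subgraph induced by the listed TFs, their edges and their targets.

    Centrality is recomputed on the subgraph. An empty survivor set yields
    an empty graph, not an error.
    """
    tf_set = set(tf_set)
    if not tf_set:
        raise ValueError("tf_set must be nonempty")
    keep_edges = [
        (u, v, d)
        for u, v, d in grn.graph.edges(data=True)
        if d["tf"] in tf_set
    ]
    G = nx.Graph()
    for u, v, d in keep_edges:
        for node in (u, v):
            G.add_node(node, kind=grn.graph.nodes[node].get("kind", "gene"))
        G.add_edge(u, v, **d)
    sub = GRNGraph(graph=G, im_percentile=grn.im_percentile)
    if G.number_of_nodes():
        betweenness(sub)
    return sub


def regulon_overlap(a: RegulonSet, b: RegulonSet) -> pd.DataFrame:
    """Per-TF size, Jaccard and size-ratio comparison of two regulon sets."""
    tfs = sorted(set(a.tfs()) | set(b.tfs()))
    rows = []
    for tf in tfs:
        sa, sb = set(a.targets(tf)), set(b.targets(tf))
        union = sa | sb
        jac = len(sa & sb) / len(union) if union else np.nan
        ratio = len(sb) / len(sa) if sa else np.nan
        rows.append((tf, len(sa), len(sb), jac, ratio))
    return pd.DataFrame(rows, columns=["tf", "size_a", "size_b", "jaccard", "size_ratio"])


class RegulonDynamicsClusterer(ClusterMixin, BaseEstimator):
    """Temporal-family clustering of regulon sizes, scikit-learn style.

    ``fit`` takes a TF x age-group size table; fitted attributes expose the
    annotated table (``table_``) and per-TF labels (``labels_``, with flat
    rows labelled ``"flat"``).
    """

    def __init__(
        self,
        k: int = 6,
        baseline: str | None = None,
        n_restarts: int = 100,
        fuzzifier: float = 2.0,
        random_state: int = 0,
    ):
        self.k = k
        self.baseline = baseline
        self.n_restarts = n_restarts
        self.fuzzifier = fuzzifier
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "RegulonDynamicsClusterer":
        self.table_ = cluster_regulon_dynamics(
            X,
            k=self.k,
            baseline=self.baseline,
            seed=self.random_state,
            n_restarts=self.n_restarts,
            fuzzifier=self.fuzzifier,
        )
        self.labels_ = self.table_["cluster"].to_numpy()
        return self
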