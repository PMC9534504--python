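"""Partition-based graph abstraction on binary regulon activity.

Cells are embedded by their binary TF-state vectors, connected in a
union-of-kNN graph under a binary dissimilarity (Jaccard by default),
partitioned with seeded Leiden community detection, and the partitions
abstracted into a coarse graph whose edge weights compare observed
inter-partition kNN edges against the expectation under random edge
placement. The partition richest in cells from the youngest age group
anchors the trajectory root; simple paths from the root to degree-one
partitions of the thresholded abstraction graph are the candidate
trajectories, along which per-TF ON-fraction changes are tested with
Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "knn_graph",
    "partition",
    "connectivity",
    "select_root",
    "extract_paths",
    "path_tf_modulation",
    "partition_summaries",
    "TrajectoryAbstraction",
]


def knn_graph(
    binary: pd.DataFrame | np.ndarray, k: int = 15, metric: str = "jaccard"
) -> nx.Graph:
    """Undirected union-of-kNN graph on cells over binary TF vectors.

    ``binary`` is cells x TFs in {0, 1}. Ties in distance are broken by
    ascending cell index (stable sort), so all-identical inputs still give
    a deterministic graph. Self-loops are never created.
    """
    X = binary.to_numpy() if isinstance(binary, pd.DataFrame) else np.asarray(binary)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    if metric not in ("jaccard", "hamming"):
        raise ValueError(f"unsupported metric {metric!r}")
    D = cdist(X, X, metric=metric)
    np.nan_to_num(D, copy=False, nan=0.0)  # identical all-zero rows
    np.fill_diagonal(D, np.inf)
    if np.isfinite(D).any() and np.ptp(D[np.isfinite(D)]) == 0:
        warnings.warn("all pairwise distances tie; neighbors chosen by cell index")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        order = np.argsort(D[i], kind="stable")[:k]
        for j in order:
            G.add_edge(i, int(j))
    return G


def partition(graph: nx.Graph, resolution: float = 0.4, seed: int = 0) -> np.ndarray:
    """Seeded Leiden community detection; labels ordered by partition size.

    Uses the RB-configuration (modularity with resolution) quality
    function. Labels run 0..(P-1) with 0 the largest partition; ties in
    size are broken by the smallest member index.
    """
    g = igraph.Graph(n=graph.number_of_nodes(), edges=list(graph.edges()))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts()
    first_member = {c: int(np.flatnonzero(raw == c)[0]) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first_member[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[c] for c in raw])


def connectivity(graph: nx.Graph, labels: np.ndarray) -> pd.DataFrame:
    """Observed/expected inter-partition edge connectivity, clipped to [0, 1].

    For partitions i != j with sizes ``n_i, n_j``, observed inter-edges
    ``e_ij``, total edges ``m`` and ``n`` cells, the expected count under
    random placement is ``E_ij = m * 2 n_i n_j / (n (n - 1))`` and
    ``c_ij = min(1, e_ij / E_ij)``; the diagonal is zero.
    """
    labels = np.asarray(labels)
    parts = np.unique(labels)
    if len(parts) < 2:
        raise ValueError("need at least two partitions")
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    sizes = {p: int((labels == p).sum()) for p in parts}
    e = pd.DataFrame(0.0, index=parts, columns=parts)
    for u, v in graph.edges():
        pu, pv = labels[u], labels[v]
        if pu != pv:
            e.loc[pu, pv] += 1
            e.loc[pv, pu] += 1
    c = pd.DataFrame(0.0, index=parts, columns=parts)
    for i in parts:
        for j in parts:
            if i == j:
                continue
            expected = m * 2.0 * sizes[i] * sizes[j] / (n * (n - 1))
            c.loc[i, j] = min(1.0, e.loc[i, j] / expected) if expected > 0 else 0.0
    return c


def partition_summaries(
    labels: np.ndarray,
    obs: pd.DataFrame,
    binary: pd.DataFrame | None = None,
    group_col: str = "age_group",
) -> pd.DataFrame:
    """Per-partition size, age-group composition and per-TF ON fractions."""
    labels = np.asarray(labels)
    rows = []
    for p in np.unique(labels):
        mask = labels == p
        comp = obs.loc[mask, group_col].astype(str).value_counts(normalize=True)
        row = {"partition": p, "size": int(mask.sum())}
        row.update({f"frac_{g}": float(comp.get(g, 0.0)) for g in obs[group_col].astype(str).unique()})
        if binary is not None:
            on = binary.loc[mask].mean(axis=0)
            row.update({f"on_{tf}": float(v) for tf, v in on.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("partition").fillna(0.0)


def select_root(summaries: pd.DataFrame, young_label: str) -> int:
    """Root = partition with the highest fraction of youngest-group cells.

    Ties are broken in favour of the larger partition, then the smaller
    partition id.
    """
    col = f"frac_{young_label}"
    if col not in summaries.columns:
        raise KeyError(f"no composition column for group {young_label!r}")
    s = summaries.sort_values([col, "size"], ascending=[False, False], kind="mergesort")
    return int(s.index[0])


def extract_paths(
    conn: pd.DataFrame, root: int, min_connectivity: float = 0.01
) -> list[list[int]]:
    """Trajectory paths from the root through the abstraction graph.

    The connectivity matrix is thresholded at ``min_connectivity``; each
    connected component of the surviving graph is then reduced to its
    maximum-connectivity spanning tree (cycles in the abstraction carry no
    trajectory information, and without this reduction a cyclic abstraction
    has no leaves at all). Paths are the unique tree paths from the root to
    every degree-one tree node. An isolated root yields the single trivial
    path ``[root]``.
    """
    A = nx.Graph()
    A.add_nodes_from(int(i) for i in conn.index)
    for i in conn.index:
        for j in conn.columns:
            if i < j and conn.loc[i, j] >= min_connectivity:
                A.add_edge(int(i), int(j), weight=float(conn.loc[i, j]))
    if A.degree(root) == 0:
        return [[int(root)]]
    T = nx.maximum_spanning_tree(A, weight="weight")
    comp = nx.node_connected_component(T, root)
    leaves = sorted(n for n in comp if T.degree(n) == 1 and n != root)
    paths = [
        [int(x) for x in nx.shortest_path(T, root, leaf)] for leaf in leaves
    ]
    return paths if paths else [[int(root)]]


def path_tf_modulation(
    binary: pd.DataFrame,
    labels: np.ndarray,
    path: list[int],
    min_delta: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-TF ON-fraction changes along consecutive partitions of a path.

    For every TF and consecutive pair (i, j) on the path, a Fisher exact
    test on the 2x2 (ON/OFF x partition) table; p-values BH-adjusted across
    TFs within the pair. The call is "up"/"down" iff the adjusted p is
    below ``alpha`` and the absolute ON-fraction change is at least
    ``min_delta``.
    """
    if len(path) < 2:
        raise ValueError("path must visit at least two partitions")
    labels = np.asarray(labels)
    rows = []
    for a, b in zip(path[:-1], path[1:]):
        ma, mb = labels == a, labels == b
        if ma.sum() < 3 or mb.sum() < 3:
            warnings.warn(f"partition pair ({a}, {b}) has < 3 cells; skipped")
            continue
        stats = []
        for tf in binary.columns:
            on_a = int(binary.loc[ma, tf].sum())
            on_b = int(binary.loc[mb, tf].sum())
            table = [[on_a, int(ma.sum()) - on_a], [on_b, int(mb.sum()) - on_b]]
            p = float(fisher_exact(table, alternative="two-sided")[1])
            delta = on_b / mb.sum() - on_a / ma.sum()
            stats.append((tf, delta, p))
        pvals = [s[2] for s in stats]
        padj = multipletests(pvals, method="fdr_bh")[1]
        for (tf, delta, p), q in zip(stats, padj):
            call = "none"
            if q < alpha and abs(delta) >= min_delta:
                call = "up" if delta > 0 else "down"
            rows.append((tf, a, b, delta, p, q, call))
    return pd.DataFrame(
        rows, columns=["tf", "node_i", "node_j", "delta_on", "p", "p_adj", "call"]
    )


@dataclass
class TrajectoryResult:
    labels: np.ndarray
    summaries: pd.DataFrame
    connectivity: pd.DataFrame
    root: int
    paths: list[list[int]]


class TrajectoryAbstraction(BaseEstimator):
    """Partition-graph trajectory abstraction, scikit-learn style.

    ``fit(binary, obs)`` builds the kNN graph, partitions it (Leiden at the
    configured resolution), scores inter-partition connectivity, selects
    the root as the partition dominated by the youngest age group, and
    extracts candidate paths.

    Attributes (after ``fit``): ``labels_``, ``connectivity_``,
    ``summaries_``, ``root_``, ``paths_``.
    """

    def __init__(
        self,
        k: int = 15,
        metric: str = "jaccard",
        resolution: float = 0.4,
        min_connectivity: float = 0.01,
        young_label: str = "infant",
        group_col: str = "age_group",
        random_state: int = 0,
    ):
        self.k = k
        self.metric = metric
        self.resolution = resolution
        self.min_connectivity = min_connectivity
        self.young_label = young_label
        self.group_col = group_col
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, obs: pd.DataFrame | None = None) -> "TrajectoryAbstraction":
        if obs is None:
            raise ValueError("per-cell metadata (obs) with age groups is required")
        graph = knn_graph(X, k=self.k, metric=self.metric)
        self.graph_ = graph
        self.labels_ = partition(graph, resolution=self.resolution, seed=self.random_state)
        self.summaries_ = partition_summaries(
            self.labels_, obs, binary=X, group_col=self.group_col
        )
        self.root_ = select_root(self.summaries_, self.young_label)
        if len(np.unique(self.labels_)) < 2:
            warnings.warn("only one partition found; trajectory is trivial")
            self.connectivity_ = pd.DataFrame(0.0, index=[self.root_], columns=[self.root_])
            self.paths_ = [[self.root_]]
            return self
        self.connectivity_ = connectivity(graph, self.labels_)
        self.paths_ = extract_paths(
            self.connectivity_, self.root_, min_connectivity=self.min_connectivity
        )
        return self

    def result_(self) -> TrajectoryResult:
        return TrajectoryResult(
            self.labels_, self.summaries_, self.connectivity_, self.root_, self.paths_
        )
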