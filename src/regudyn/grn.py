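"""Consensus gene-regulatory-network inference and motif pruning.

The inference follows the stochastic tree-ensemble recipe used by
GRNBoost2-style tools: each target gene's normalized expression is regressed
on the expression of all transcription factors with a seeded randomized
ensemble, per-TF split importances form the importance metric (IM), and the
top-k TF->target pairs per target are emitted per run. Because single runs
are stochastic, many runs are aggregated into a consensus that keeps only
pairs recurring in at least a retention fraction of runs (inclusive) and
averages IM over the runs where each pair appeared (left-outer-join
semantics). The consensus is finally pruned against a cis-regulatory motif
prior: edges without motif support are dropped, TFs annotated with fewer
than ``min_motifs_per_tf`` motifs are removed entirely, and undersized
regulons are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.ensemble import ExtraTreesRegressor, GradientBoostingRegressor

from .qc import LAYER

logger = logging.getLogger(__name__)

__all__ = [
    "infer_run",
    "consensus",
    "prune_with_motifs",
    "regulon_size_table",
    "RegulonSet",
    "ConsensusGRN",
]


@dataclass
class RegulonSet:
    """Motif-pruned TF regulons: per TF an IM-ordered target table."""

    table: pd.DataFrame  # columns: tf, target, mean_im, window

    def tfs(self) -> list[str]:
        return sorted(self.table["tf"].unique())

    def targets(self, tf: str) -> list[str]:
        return self.table.loc[self.table["tf"] == tf, "target"].tolist()

    def sizes(self) -> pd.Series:
        return self.table.groupby("tf").size()

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.table["tf"], self.table["target"]))

    def as_gmt(self) -> str:
        lines = []
        for tf in self.tfs():
            lines.append("\t".join([tf, "regulon"] + self.targets(tf)))
        return "\n".join(lines) + "\n"


def _expr_matrix(adata: ad.AnnData, layer: str) -> np.ndarray:
    X = adata.layers[layer] if layer in adata.layers else None
    if X is None:
        raise ValueError("normalized layer missing; run normalize_log first")
    return np.asarray(X.toarray() if sp.issparse(X) else X, dtype=np.float32)


def _make_learner(learner: str, seed: int, **kw):
    if learner == "extratrees":
        return ExtraTreesRegressor(
            n_estimators=kw.get("n_estimators", 10),
            max_features=kw.get("max_features", "sqrt"),
            max_depth=kw.get("max_depth", 5),
            random_state=seed,
            n_jobs=1,
        )
    if learner == "gbm":
        return GradientBoostingRegressor(
            n_estimators=kw.get("n_estimators", 50),
            subsample=kw.get("subsample", 0.9),
            max_depth=kw.get("max_depth", 3),
            random_state=seed,
        )
    raise ValueError(f"unknown learner {learner!r}")


def infer_run(
    adata: ad.AnnData,
    tf_list: Sequence[str],
    seed: int = 0,
    top_k_per_target: int = 50,
    layer: str = LAYER,
    learner: str = "extratrees",
    subsample_cells: int | None = 500,
    **learner_kw,
) -> pd.DataFrame:
    """One stochastic TF->target importance run.

    For every non-TF gene with nonzero variance, fits a seeded randomized
    tree-ensemble regression of its expression on all TF expressions and
    emits the ``top_k_per_target`` positive-importance pairs. Cells are
    subsampled (without replacement) per run both for speed and to
    diversify runs. Identical seeds give identical tables.
    """
    tf_list = [t for t in tf_list if t in adata.var_names]
    if not tf_list:
        raise ValueError("no TF from tf_list present in the matrix")
    X = _expr_matrix(adata, layer)
    rng = np.random.default_rng(seed)
    if subsample_cells is not None and subsample_cells < X.shape[0]:
        rows = rng.choice(X.shape[0], size=subsample_cells, replace=False)
        X = X[rows]
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    tf_cols = np.asarray([var_index[t] for t in tf_list])
    tf_X = X[:, tf_cols]
    targets = [g for g in adata.var_names if g not in set(tf_list)]

    records: list[tuple[str, str, float]] = []
    for g in targets:
        y = X[:, var_index[g]]
        if np.ptp(y) == 0:
            logger.debug("target %s has zero variance; no edges emitted", g)
            continue
        model = _make_learner(learner, int(rng.integers(2**31)), **learner_kw)
        model.fit(tf_X, y)
        imp = model.feature_importances_
        order = np.argsort(-imp)[:top_k_per_target]
        for i in order:
            if imp[i] <= 0:
                break
            records.append((tf_list[i], g, float(imp[i])))
    table = pd.DataFrame(records, columns=["tf", "target", "im"])
    table["run_seed"] = seed
    return table


def consensus(
    tables: Iterable[pd.DataFrame], retention_threshold: float = 0.8
) -> pd.DataFrame:
    """Aggregate per-run edge tables into a consensus table.

    ``retention_freq`` is the fraction of runs containing the pair; pairs
    are retained iff ``retention_freq >= retention_threshold`` (inclusive:
    16 of 20 runs survives a 0.8 threshold). ``mean_im`` averages IM over
    the runs where the pair appeared, never imputing zeros for absences.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("consensus needs at least two run tables")
    n_runs = len(tables)
    stacked = pd.concat(
        [t[["tf", "target", "im"]] for t in tables], keys=range(n_runs), names=["run"]
    ).reset_index(level="run")
    grouped = stacked.groupby(["tf", "target"], sort=True).agg(
        n_present=("run", "nunique"), mean_im=("im", "mean")
    )
    if grouped.empty:
        raise ValueError("no edges present in any run")
    grouped["retention_freq"] = grouped["n_present"] / n_runs
    kept = grouped[grouped["retention_freq"] >= retention_threshold].reset_index()
    out = kept[["tf", "target", "retention_freq", "mean_im"]].copy()
    out.attrs["n_runs"] = n_runs
    out.attrs["retention_threshold"] = retention_threshold
    return out


def prune_with_motifs(
    consensus_table: pd.DataFrame,
    prior: pd.DataFrame,
    min_motifs_per_tf: int = 2,
    min_regulon_size: int = 10,
) -> RegulonSet:
    """Keep consensus edges with motif support; build regulons.

    An edge survives iff its target appears in the TF's motif-supported
    gene set in at least one window. TFs whose motif count is below
    ``min_motifs_per_tf`` are removed entirely (guards against wrongly
    annotated single-motif TFs), and regulons smaller than
    ``min_regulon_size`` are dropped. Output sorted by TF then descending
    mean IM.
    """
    if prior.empty:
        raise ValueError("motif prior is empty")
    motif_counts = prior.groupby("tf")["n_motifs"].max()
    good_tfs = set(motif_counts[motif_counts >= min_motifs_per_tf].index)
    prior_pairs = prior.groupby(["tf", "target"])["window"].agg(
        lambda s: ";".join(sorted(set(s)))
    )
    rows = []
    for _, row in consensus_table.iterrows():
        tf, tg = row["tf"], row["target"]
        if tf not in set(motif_counts.index):
            logger.debug("TF %s absent from motif prior; edges dropped", tf)
            continue
        if tf not in good_tfs:
            continue
        key = (tf, tg)
        if key in prior_pairs.index:
            rows.append((tf, tg, float(row["mean_im"]), prior_pairs[key]))
    table = pd.DataFrame(rows, columns=["tf", "target", "mean_im", "window"])
    sizes = table.groupby("tf")["target"].transform("size")
    table = table[sizes >= min_regulon_size]
    table = table.sort_values(["tf", "mean_im"], ascending=[True, False]).reset_index(drop=True)
    return RegulonSet(table)


def regulon_size_table(
    regulons_by_group: Mapping[str, RegulonSet], groups: Sequence[str] | None = None
) -> pd.DataFrame:
    """TF x age-group table of regulon sizes (target counts); absent = 0."""
    if not regulons_by_group:
        raise ValueError("need at least one group")
    groups = list(groups) if groups is not None else list(regulons_by_group)
    tfs = sorted({tf for rs in regulons_by_group.values() for tf in rs.tfs()})
    out = pd.DataFrame(0, index=tfs, columns=groups, dtype=int)
    for g in groups:
        sizes = regulons_by_group[g].sizes()
        out.loc[sizes.index, g] = sizes
    return out


class ConsensusGRN(BaseEstimator):
    """Consensus GRN inference as a scikit-learn style estimator.

    Fitting runs ``n_runs`` seeded stochastic importance inferences on the
    normalized expression layer, aggregates them by retention frequency and
    prunes the consensus against a motif prior.

    Parameters
    ----------
    tf_list : sequence of str
        Transcription-factor gene names.
    prior : DataFrame, optional
        Motif prior (``tf, target, n_motifs, window``). When omitted, the
        fitted attributes stop at the consensus table.
    n_runs : int
        Number of stochastic runs (production analyses typically use 100;
        the default keeps desk-scale experiments fast).
    retention_threshold : float
        Inclusive retention-frequency cutoff.

    Attributes
    ----------
    run_tables_ : list of DataFrame
    consensus_ : DataFrame
    regulons_ : RegulonSet (when a prior was given)
    """

    def __init__(
        self,
        tf_list: Sequence[str] = (),
        prior: pd.DataFrame | None = None,
        n_runs: int = 20,
        retention_threshold: float = 0.8,
        top_k_per_target: int = 50,
        min_motifs_per_tf: int = 2,
        min_regulon_size: int = 10,
        learner: str = "extratrees",
        subsample_cells: int | None = 500,
        layer: str = LAYER,
        random_state: int = 0,
    ):
        self.tf_list = tf_list
        self.prior = prior
        self.n_runs = n_runs
        self.retention_threshold = retention_threshold
        self.top_k_per_target = top_k_per_target
        self.min_motifs_per_tf = min_motifs_per_tf
        self.min_regulon_size = min_regulon_size
        self.learner = learner
        self.subsample_cells = subsample_cells
        self.layer = layer
        self.random_state = random_state

    def fit(self, X: ad.AnnData, y=None) -> "ConsensusGRN":
        rng = np.random.default_rng(self.random_state)
        run_seeds = [int(s) for s in rng.integers(2**31, size=self.n_runs)]
        self.run_tables_ = [
            infer_run(
                X,
                self.tf_list,
                seed=s,
                top_k_per_target=self.top_k_per_target,
                layer=self.layer,
                learner=self.learner,
                subsample_cells=self.subsample_cells,
            )
            for s in run_seeds
        ]
        self.consensus_ = consensus(self.run_tables_, self.retention_threshold)
        if self.prior is not None:
            self.regulons_ = prune_with_motifs(
                self.consensus_,
                self.prior,
                min_motifs_per_tf=self.min_motifs_per_tf,
                min_regulon_size=self.min_regulon_size,
            )
        return self
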