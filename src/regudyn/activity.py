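"""Regulon activity scoring (recovery-curve AUC), binarization and
TF-activity correlation structure.

Per cell, genes are ranked by descending normalized expression (ties broken
by a seeded random permutation so results are reproducible without index
bias). The recovery curve counts how many of a regulon's genes appear among
the top ``i`` ranks; summing it over the top ``ceil(top_fraction * n_genes)``
ranks and dividing by the maximum attainable sum (all regulon genes at the
very top) gives a per-cell activity score in [0, 1]. Activities are
binarized into ON/OFF per regulon with a bimodal-mixture threshold on the
AUC distribution across cells; unimodal regulons fall back to the 99th
percentile so that a regulon without bimodal signal is conservatively OFF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin

from .grn import RegulonSet
from .qc import LAYER, bimodal_threshold

__all__ = [
    "ActivityMatrix",
    "aucell_score",
    "binarize",
    "tf_activity_correlation",
    "AUCellScorer",
    "RegulonBinarizer",
]


@dataclass
class ActivityMatrix:
    """Regulon x cell activity: AUC scores, thresholds and ON/OFF calls."""

    auc: pd.DataFrame  # regulons x cells, values in [0, 1]
    top_fraction: float
    thresholds: pd.Series | None = None
    binary: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _rank_matrix(X: np.ndarray, seed: int) -> np.ndarray:
    """1-based descending-expression ranks per cell, seeded random ties."""
    rng = np.random.default_rng(seed)
    n_cells, n_genes = X.shape
    ranks = np.empty((n_cells, n_genes), dtype=np.int32)
    for i in range(n_cells):
        perm = rng.permutation(n_genes)
        order = np.lexsort((perm, -X[i]))
        ranks[i, order] = np.arange(1, n_genes + 1)
    return ranks


def _regulon_gene_lists(
    regulons: RegulonSet | dict, var_names: pd.Index
) -> dict[str, list[str]]:
    if isinstance(regulons, RegulonSet):
        raw = {tf: regulons.targets(tf) for tf in regulons.tfs()}
    else:
        raw = {k: list(v) for k, v in regulons.items()}
    present = set(var_names)
    out: dict[str, list[str]] = {}
    for name, genes in raw.items():
        kept = [g for g in genes if g in present]
        if len(kept) < len(genes):
            warnings.warn(
                f"regulon {name!r}: {len(genes) - len(kept)} genes absent from the matrix"
            )
        if not kept:
            raise ValueError(f"regulon {name!r} has no genes present in the matrix")
        out[name] = kept
    return out


def aucell_score(
    adata: ad.AnnData,
    regulons: RegulonSet | dict,
    top_fraction: float = 0.05,
    seed: int = 0,
    layer: str = LAYER,
) -> ActivityMatrix:
    """Score each regulon in each cell by recovery-curve AUC.

    ``raw = sum_{i=1..k} hits(i)`` where ``hits(i)`` is the number of
    regulon genes among the top ``i`` ranks and ``k = ceil(top_fraction *
    n_genes)``; the score is ``raw`` divided by its maximum (regulon genes
    occupying ranks 1..|R|), hence in [0, 1]. Being rank-based, scores are
    invariant to monotone transforms of a cell's expression values.
    """
    if layer not in adata.layers:
        raise ValueError("normalized layer missing; run normalize_log first")
    gene_lists = _regulon_gene_lists(regulons, adata.var_names)
    X = adata.layers[layer]
    X = np.asarray(X.toarray() if sp.issparse(X) else X, dtype=np.float64)
    n_genes = X.shape[1]
    k = int(np.ceil(top_fraction * n_genes))
    if k < 1:
        raise ValueError("top_fraction too small: the top-rank window is empty")
    ranks = _rank_matrix(X, seed)
    col = {g: j for j, g in enumerate(adata.var_names)}
    auc = {}
    for name, genes in gene_lists.items():
        r = ranks[:, [col[g] for g in genes]]
        contrib = np.clip(k - r + 1, 0, None)
        raw = contrib.sum(axis=1)
        m = min(len(genes), k)
        max_raw = m * k - m * (m - 1) // 2  # sum_{j=1..m} (k - j + 1)
        auc[name] = raw / max_raw
    df = pd.DataFrame(auc, index=adata.obs_names).T
    return ActivityMatrix(auc=df, top_fraction=top_fraction, meta={"k": k, "seed": seed})


def binarize(activity: ActivityMatrix, random_state: int = 0) -> ActivityMatrix:
    """ON/OFF calls per regulon via a bimodal threshold on its AUCs.

    When BIC model selection prefers a single component, the threshold
    falls back to the regulon's 99th AUC percentile, so nearly every cell
    is OFF; constant AUC rows are all OFF. ``binary[r, c] = 1`` iff
    ``auc[r, c] > threshold[r]`` (strict).
    """
    thresholds = {}
    for name, row in activity.auc.iterrows():
        vals = row.to_numpy()
        if vals.size < 20:  # too few cells for a mixture fit: conservative OFF
            t = float("inf")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = bimodal_threshold(vals, random_state=random_state)
        if np.isinf(t):
            t = float(np.percentile(vals, 99))
        thresholds[name] = t
    thr = pd.Series(thresholds)
    binary = (activity.auc.gt(thr, axis=0)).astype(np.int8)
    activity.thresholds = thr
    activity.binary = binary
    return activity


def tf_activity_correlation(
    activity: ActivityMatrix, layer: str = "auc"
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """TF x TF Pearson correlation of activities plus a two-way HCA cut.

    Correlates regulon activity rows over cells (AUC layer by default,
    binary via ``layer='binary'``), clusters on ``1 - r`` with average
    linkage and reports the two top-level clades as ``{1: [...], 2: [...]}``.
    Zero-variance rows are excluded with a warning.
    """
    M = activity.auc if layer == "auc" else activity.binary
    if M is None:
        raise ValueError(f"layer {layer!r} not computed")
    if M.shape[0] < 2 or M.shape[1] < 3:
        raise ValueError("need at least 2 regulons and 3 cells")
    spans = M.apply(np.ptp, axis=1)
    dropped = spans[spans == 0].index.tolist()
    if dropped:
        warnings.warn(f"zero-variance regulons excluded: {dropped}")
    Mv = M.drop(index=dropped)
    names = Mv.index.tolist()
    r = np.corrcoef(Mv.to_numpy())
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=names, columns=names)
    dist = hierarchy.distance.squareform(1.0 - r, checks=False)
    Z = hierarchy.linkage(dist, method="average")
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    clades = {c: [names[i] for i in np.flatnonzero(cut == c)] for c in (1, 2)}
    return corr, clades


class AUCellScorer(TransformerMixin, BaseEstimator):
    """Recovery-curve AUC scoring as a scikit-learn transformer.

    ``transform`` maps an AnnData with a normalized layer to a regulon x
    cell :class:`ActivityMatrix`.
    """

    def __init__(
        self,
        regulons: RegulonSet | dict | None = None,
        top_fraction: float = 0.05,
        layer: str = LAYER,
        random_state: int = 0,
    ):
        self.regulons = regulons
        self.top_fraction = top_fraction
        self.layer = layer
        self.random_state = random_state

    def fit(self, X: ad.AnnData, y=None) -> "AUCellScorer":
        if self.regulons is None:
            raise ValueError("regulons must be provided")
        self.regulon_genes_ = _regulon_gene_lists(self.regulons, X.var_names)
        return self

    def transform(self, X: ad.AnnData) -> ActivityMatrix:
        return aucell_score(
            X,
            self.regulons,
            top_fraction=self.top_fraction,
            seed=self.random_state,
            layer=self.layer,
        )


class RegulonBinarizer(TransformerMixin, BaseEstimator):
    """Per-regulon ON/OFF binarization of AUC activities.

    ``fit`` learns per-regulon thresholds (bimodal mixture, with a
    99th-percentile unimodal fallback); ``transform`` applies them.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X: ActivityMatrix, y=None) -> "RegulonBinarizer":
        binarize(X, random_state=self.random_state)
        self.thresholds_ = X.thresholds
        return self

    def transform(self, X: ActivityMatrix) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise ValueError("RegulonBinarizer is not fitted")
        binary = X.auc.gt(self.thresholds_.reindex(X.auc.index), axis=0).astype(np.int8)
        X.thresholds = self.thresholds_
        X.binary = binary
        return binary
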