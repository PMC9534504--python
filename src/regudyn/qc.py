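"""Quality control, normalization and cluster-marker statistics.

Implements the preprocessing conventions common to multi-study pancreatic
islet scRNA-seq analyses: per-cell detected-gene and mitochondrial-fraction
filters, a min-cells gene filter applied after the cell filter, library-size
log-normalization to a fixed molecule scale, Gaussian-mixture bimodal
thresholds for marker-coexpression doublet exclusion (computed independently
per study), pseudobulk group correlation with average-linkage clustering,
and Wilcoxon rank-sum cluster markers with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.optimize import brentq
from scipy.stats import mannwhitneyu, norm
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCReport",
    "filter_cells_genes",
    "normalize_log",
    "bimodal_threshold",
    "flag_coexpression_doublets",
    "pseudobulk_group_correlation",
    "rank_markers",
]

LAYER = "lognorm"


@dataclass
class QCReport:
    """Bookkeeping for one filtering pass."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_low_genes: int
    removed_high_genes: int
    removed_high_mito: int
    removed_genes_min_cells: int
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "removed_low_genes": self.removed_low_genes,
            "removed_high_genes": self.removed_high_genes,
            "removed_high_mito": self.removed_high_mito,
            "removed_genes_min_cells": self.removed_genes_min_cells,
            "thresholds": self.thresholds,
        }


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def filter_cells_genes(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 8000,
    max_mito_frac: float = 0.25,
    min_cells_per_gene: int = 3,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, QCReport]:
    """Drop low-quality cells, then genes detected in too few cells.

    A cell is kept when its detected-gene count lies in
    ``[min_genes, max_genes]`` and its mitochondrial count fraction is at
    most ``max_mito_frac``. Genes must then be detected in at least
    ``min_cells_per_gene`` of the *retained* cells. Mitochondrial genes are
    recognized by the ``is_mito`` var column when present, otherwise by
    name prefix.
    """
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    if "is_mito" in adata.var:
        mito_mask = adata.var["is_mito"].to_numpy(dtype=bool)
    else:
        mito_mask = adata.var_names.str.startswith(mito_prefix).to_numpy()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)

    low = detected < min_genes
    high = detected > max_genes
    mito_bad = mito_frac > max_mito_frac
    keep_cells = ~(low | high | mito_bad)
    if not keep_cells.any():
        raise ValueError("all cells removed by quality filters")

    sub = adata[keep_cells].copy()
    Xk = sub.X.tocsr() if sp.issparse(sub.X) else sp.csr_matrix(sub.X)
    gene_cells = np.asarray((Xk > 0).sum(axis=0)).ravel()
    keep_genes = gene_cells >= min_cells_per_gene
    out = sub[:, keep_genes].copy()

    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=out.n_obs,
        n_genes_in=adata.n_vars,
        n_genes_out=out.n_vars,
        removed_low_genes=int(low.sum()),
        removed_high_genes=int(high.sum()),
        removed_high_mito=int(mito_bad.sum()),
        removed_genes_min_cells=int((~keep_genes).sum()),
        thresholds={
            "min_genes": min_genes,
            "max_genes": max_genes,
            "max_mito_frac": max_mito_frac,
            "min_cells_per_gene": min_cells_per_gene,
        },
    )
    return out, report


def normalize_log(adata: ad.AnnData, scale: float = 1e4, layer: str = LAYER) -> ad.AnnData:
    """Library-size normalize to ``scale`` molecules per cell and log1p.

    ``normalized[g, c] = ln(1 + counts[g, c] / libsize(c) * scale)``,
    stored in ``adata.layers[layer]``. Zero-library cells are an error.
    """
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    libsize = np.asarray(X.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero library size: {list(adata.obs_names[zero[:5]])}"
        )
    norm_counts = X.multiply(scale / libsize[:, None]).tocsr()
    norm_counts.data = np.log1p(norm_counts.data)
    adata.layers[layer] = norm_counts
    return adata


def _gmm_crossing(w: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Posterior-equality point between the two component means."""
    lo, hi = float(min(mu)), float(max(mu))

    def diff(x: float) -> float:
        return w[0] * norm.pdf(x, mu[0], sigma[0]) - w[1] * norm.pdf(x, mu[1], sigma[1])

    # densities of the low component dominate at its mean and vice versa in
    # the bimodal regime; if not, fall back to the weighted midpoint.
    order = np.argsort(mu)
    lo_i, hi_i = order
    f_lo = w[lo_i] * norm.pdf(lo, mu[lo_i], sigma[lo_i]) - w[hi_i] * norm.pdf(lo, mu[hi_i], sigma[hi_i])
    f_hi = w[lo_i] * norm.pdf(hi, mu[lo_i], sigma[lo_i]) - w[hi_i] * norm.pdf(hi, mu[hi_i], sigma[hi_i])
    if f_lo > 0 > f_hi:
        sign = 1.0 if lo_i == 0 else -1.0
        return float(brentq(lambda x: sign * diff(x), lo, hi))
    return float((mu[lo_i] + mu[hi_i]) / 2.0)


def bimodal_threshold(values: np.ndarray, random_state: int = 0) -> float:
    """Threshold separating the two modes of a bimodal distribution.

    Fits one- and two-component Gaussian mixtures; when BIC prefers two
    components, the threshold is the point between the component means where
    the posteriors cross. When one component is preferred (or the input is
    degenerate) returns ``+inf`` so that no observation is called high.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 20:
        raise ValueError("need at least 20 values to fit a bimodal threshold")
    if np.ptp(values) == 0 or np.std(values) < 1e-12:
        warnings.warn("degenerate (zero-variance) input; returning +inf threshold")
        return float("inf")
    X = values.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=random_state).fit(X)
    g2 = GaussianMixture(2, random_state=random_state, n_init=3).fit(X)
    if g1.bic(X) <= g2.bic(X):
        return float("inf")
    w = g2.weights_.ravel()
    mu = g2.means_.ravel()
    sigma = np.sqrt(g2.covariances_.ravel())
    return _gmm_crossing(w, mu, sigma)


def flag_coexpression_doublets(
    adata: ad.AnnData,
    gene_a: str,
    gene_b: str,
    study_col: str = "study",
    layer: str = LAYER,
    exempt_age_groups: tuple[str, ...] = (),
    random_state: int = 0,
) -> pd.Series:
    """Flag cells expressing *both* marker genes above bimodal thresholds.

    Thresholds are computed independently within each dataset (``study``
    metadata value). Cells from ``exempt_age_groups`` are never flagged and
    are excluded from threshold fitting.
    """
    for g in (gene_a, gene_b):
        if g not in adata.var_names:
            raise KeyError(f"gene {g!r} not present in the matrix")
    if layer not in adata.layers:
        raise ValueError("normalized layer missing; run normalize_log first")
    expr = {
        g: _dense(adata[:, g].layers[layer]).ravel() for g in (gene_a, gene_b)
    }
    exempt = (
        adata.obs["age_group"].astype(str).isin(exempt_age_groups).to_numpy()
        if exempt_age_groups and "age_group" in adata.obs
        else np.zeros(adata.n_obs, dtype=bool)
    )
    flags = pd.Series(False, index=adata.obs_names)
    for study, idx in adata.obs.groupby(study_col, observed=True).groups.items():
        mask = np.asarray(adata.obs_names.isin(idx)) & ~exempt
        if mask.sum() < 20:
            warnings.warn(f"study {study!r} has too few cells for thresholding; skipped")
            continue
        ta = bimodal_threshold(expr[gene_a][mask], random_state=random_state)
        tb = bimodal_threshold(expr[gene_b][mask], random_state=random_state)
        hit = mask & (expr[gene_a] > ta) & (expr[gene_b] > tb)
        flags[hit] = True
    return flags


def pseudobulk_group_correlation(
    adata: ad.AnnData, grouping: str, layer: str = LAYER
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of per-group mean expression profiles.

    Groups with zero cells are excluded with a warning. Returns the
    symmetric correlation matrix (unit diagonal) and the leaf order of an
    average-linkage dendrogram computed on ``1 - r`` distances.
    """
    if layer not in adata.layers:
        raise ValueError("normalized layer missing; run normalize_log first")
    labels = adata.obs[grouping].astype(str)
    groups = [g for g in labels.unique()]
    profiles = {}
    for g in groups:
        mask = (labels == g).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"group {g!r} has no cells; excluded")
            continue
        profiles[g] = np.asarray(_dense(adata.layers[layer][mask]).mean(axis=0)).ravel()
    if len(profiles) < 2:
        raise ValueError("need at least two non-empty groups")
    names = list(profiles)
    P = np.vstack([profiles[g] for g in names])
    r = np.corrcoef(P)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=names, columns=names)
    dist = hierarchy.distance.squareform(1.0 - r, checks=False)
    Z = hierarchy.linkage(dist, method="average")
    order = [names[i] for i in hierarchy.leaves_list(Z)]
    return corr, order


def _ranksum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided rank-sum p; exact when both groups are small and tie-free."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not ties:
        return float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def rank_markers(
    adata: ad.AnnData, labels: str | pd.Series, layer: str = LAYER
) -> pd.DataFrame:
    """Per-cluster marker genes by two-sided Wilcoxon rank-sum vs rest.

    Effect is the log2 fold change of the de-logged group means (pseudo
    1e-9). P-values are Benjamini-Hochberg adjusted across genes within each
    cluster; rows sorted by adjusted p then descending effect.
    """
    if layer not in adata.layers:
        raise ValueError("normalized layer missing; run normalize_log first")
    lab = adata.obs[labels].astype(str) if isinstance(labels, str) else pd.Series(labels).astype(str)
    lab.index = adata.obs_names
    clusters = sorted(lab.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    X = _dense(adata.layers[layer])
    rows = []
    for cl in clusters:
        mask = (lab == cl).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"cluster {cl!r} has fewer than 3 cells; skipped")
            continue
        A, B = X[mask], X[~mask]
        pvals = np.empty(adata.n_vars)
        effects = np.empty(adata.n_vars)
        for j in range(adata.n_vars):
            a, b = A[:, j], B[:, j]
            if np.ptp(np.concatenate([a, b])) == 0:
                pvals[j], effects[j] = 1.0, 0.0
                continue
            pvals[j] = _ranksum_p(a, b)
            ma, mb = np.expm1(a).mean(), np.expm1(b).mean()
            effects[j] = np.log2((ma + 1e-9) / (mb + 1e-9))
        padj = multipletests(pvals, method="fdr_bh")[1]
        for j, g in enumerate(adata.var_names):
            rows.append((g, cl, effects[j], pvals[j], padj[j]))
    out = pd.DataFrame(rows, columns=["gene", "cluster", "effect", "p", "p_adj"])
    return out.sort_values(
        ["cluster", "p_adj", "effect"], ascending=[True, True, False]
    ).reset_index(drop=True)
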