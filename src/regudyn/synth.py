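"""Synthetic single-cell datasets with planted regulatory structure.

The generator emulates the statistical features of droplet/plate scRNA-seq
count data that the downstream regulon pipeline depends on:

* negative-binomial counts with gene-level baseline means drawn from a gamma
  distribution and lognormal cell-level library-size factors;
* planted transcription-factor (TF) -> target regulons with per-cell ON/OFF
  TF states sampled per age group, where an ON TF multiplies the mean of its
  responsive targets (and its own mean) by an effect size ``beta > 1``;
* age-group-dependent regulon rewiring: each edge exists globally but is
  *responsive* only in a configurable subset of age groups;
* two mutually exclusive marker genes (one per simulated cell type), so that
  coexpression-based doublet exclusion has a planted signal;
* doublet cells spiked in as element-wise sums of one parent cell of each
  type.

Every random draw flows through one :class:`numpy.random.Generator` seeded
from the configuration, so identical configurations produce bit-identical
datasets and ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_motif_prior",
    "spike_doublets",
    "aging_trajectory_scenario",
    "write_dataset",
]

MARKER_A = "MARKER_A"
MARKER_B = "MARKER_B"

# Age (years) sampled uniformly within these bounds per default group.
_DEFAULT_AGE_RANGES = {"infant": (0, 5), "adult": (20, 59), "old": (61, 90)}


@dataclass
class SynthConfig:
    """Configuration of the planted-regulon count generator.

    Parameters
    ----------
    n_tfs, n_targets_per_tf, n_noise_genes
        Gene-universe dimensions. Total genes =
        ``n_tfs * (1 + n_targets_per_tf) + n_noise_genes + 2`` (two marker
        genes).
    n_cells_per_group
        Cells simulated per age group (before doublet spiking).
    age_groups
        Ordered labels, youngest first.
    beta
        Fold-change multiplier applied to a target's mean when its
        regulating TF is ON (must exceed 1, otherwise there is no signal).
    on_prob
        Probability that a TF is ON in a cell; either a scalar, a mapping
        ``group -> prob``, or a mapping ``group -> {tf_name: prob}``.
    rewiring_map
        ``group -> {tf_name: sequence of responsive target names}``. TFs or
        groups absent from the mapping keep their full target set
        responsive.
    nb_dispersion
        Negative-binomial size parameter theta (variance = mu + mu^2/theta).
    libsize_lognormal
        ``(mu, sigma)`` of the lognormal cell-level library-size factor.
    doublet_rate
        Fraction of cells spiked in as synthetic doublets
        (``floor(rate * n_cells)`` cells are appended).
    seed
        Master seed; drives every random draw.
    """

    n_tfs: int = 10
    n_targets_per_tf: int = 10
    n_noise_genes: int = 100
    n_cells_per_group: int = 300
    age_groups: tuple[str, ...] = ("infant", "adult", "old")
    beta: float = 4.0
    on_prob: float | Mapping[str, float] | Mapping[str, Mapping[str, float]] = 0.5
    rewiring_map: Mapping[str, Mapping[str, Sequence[str]]] | None = None
    nb_dispersion: float = 2.0
    libsize_lognormal: tuple[float, float] = (0.0, 0.3)
    doublet_rate: float = 0.0
    n_studies: int = 1
    n_donors_per_group: int = 2
    seed: int = 0
    base_mean_gamma: tuple[float, float] = (2.0, 1.0)  # (shape, scale)
    marker_high_mean: float = 60.0
    marker_low_mean: float = 0.05

    def validate(self) -> None:
        for name in ("n_tfs", "n_targets_per_tf", "n_cells_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be nonnegative")
        if not self.beta > 1.0:
            raise ValueError(f"beta must exceed 1, got {self.beta}")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ValueError("doublet_rate must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for p in np.atleast_1d(np.asarray(self._flat_probs(), dtype=float)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"on_prob values must lie in [0, 1], got {p}")

    def _flat_probs(self) -> list[float]:
        if isinstance(self.on_prob, Mapping):
            out: list[float] = []
            for v in self.on_prob.values():
                if isinstance(v, Mapping):
                    out.extend(float(x) for x in v.values())
                else:
                    out.append(float(v))
            return out
        return [float(self.on_prob)]

    def tf_names(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    def target_names(self, tf: str) -> list[str]:
        return [f"{tf}.T{j:02d}" for j in range(1, self.n_targets_per_tf + 1)]

    def noise_names(self) -> list[str]:
        return [f"NOISE{i:04d}" for i in range(1, self.n_noise_genes + 1)]

    def gene_names(self) -> list[str]:
        genes: list[str] = []
        for tf in self.tf_names():
            genes.append(tf)
            genes.extend(self.target_names(tf))
        genes.extend(self.noise_names())
        genes.extend([MARKER_A, MARKER_B])
        return genes

    def on_prob_for(self, tf: str, group: str) -> float:
        p = self.on_prob
        if isinstance(p, Mapping):
            v = p[group]
            if isinstance(v, Mapping):
                return float(v.get(tf, 0.5))
            return float(v)
        return float(p)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    edges: list[tuple[str, str, tuple[str, ...]]]
    tf_state: pd.DataFrame  # cells x TFs, {0,1}
    doublet_flags: pd.Series  # per cell, bool
    marker_genes: tuple[str, str] = (MARKER_A, MARKER_B)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(tf, tg) for tf, tg, _ in self.edges}

    def active_edges(self, group: str) -> set[tuple[str, str]]:
        return {(tf, tg) for tf, tg, groups in self.edges if group in groups}

    def to_json(self) -> str:
        payload = {
            "edges": [[tf, tg, list(groups)] for tf, tg, groups in self.edges],
            "tf_state": {
                "cells": self.tf_state.index.tolist(),
                "tfs": self.tf_state.columns.tolist(),
                "values": self.tf_state.to_numpy().astype(int).tolist(),
            },
            "doublet_flags": self.doublet_flags.astype(int).to_dict(),
            "marker_genes": list(self.marker_genes),
        }
        return json.dumps(payload)


def _responsive_targets(config: SynthConfig, tf: str, group: str) -> list[str]:
    full = config.target_names(tf)
    if config.rewiring_map is None:
        return full
    group_map = config.rewiring_map.get(group)
    if group_map is None or tf not in group_map:
        return full
    subset = list(group_map[tf])
    unknown = set(subset) - set(full)
    if unknown:
        raise ValueError(f"rewiring_map for {tf}/{group} lists unknown targets: {sorted(unknown)}")
    return subset


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB(mu, theta) via gamma-Poisson mixture; supports an array of means."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def generate_dataset(config: SynthConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate a count matrix with planted regulons and ground truth.

    Returns an :class:`anndata.AnnData` (cells x genes) whose ``X`` layer
    holds raw integer counts and whose ``obs`` carries donor, age,
    age-group, sex, study and cell-type metadata, together with the
    :class:`SyntheticTruth` describing the planted structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = config.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    tfs = config.tf_names()
    n_genes = len(genes)

    # Gene-level baseline means (gamma), shared across cells.
    shape, scale = config.base_mean_gamma
    base_mean = rng.gamma(shape=shape, scale=scale, size=n_genes) + 0.05
    base_mean[gene_index[MARKER_A]] = config.marker_low_mean
    base_mean[gene_index[MARKER_B]] = config.marker_low_mean

    groups = list(config.age_groups)
    n_cells = config.n_cells_per_group * len(groups)
    cell_names = [f"cell{i:05d}" for i in range(n_cells)]

    # Metadata ------------------------------------------------------------
    age_group = np.repeat(groups, config.n_cells_per_group)
    ages = np.empty(n_cells)
    donors = np.empty(n_cells, dtype=object)
    donor_counter = 0
    for gi, g in enumerate(groups):
        lo, hi = _DEFAULT_AGE_RANGES.get(g, (10 + 30 * gi, 20 + 30 * gi))
        sl = slice(gi * config.n_cells_per_group, (gi + 1) * config.n_cells_per_group)
        donor_ids = [f"donor{donor_counter + d:02d}" for d in range(config.n_donors_per_group)]
        donor_counter += config.n_donors_per_group
        donor_ages = rng.uniform(lo, hi, size=config.n_donors_per_group)
        pick = rng.integers(0, config.n_donors_per_group, size=config.n_cells_per_group)
        donors[sl] = np.asarray(donor_ids, dtype=object)[pick]
        ages[sl] = donor_ages[pick]
    sex = rng.choice(["F", "M"], size=n_cells)
    studies = np.asarray([f"study{1 + i % config.n_studies}" for i in range(n_cells)])
    rng.shuffle(studies)
    cell_type = rng.choice(["typeA", "typeB"], size=n_cells)

    # TF states -----------------------------------------------------------
    tf_state = np.zeros((n_cells, len(tfs)), dtype=np.int8)
    for ti, tf in enumerate(tfs):
        for gi, g in enumerate(groups):
            sl = slice(gi * config.n_cells_per_group, (gi + 1) * config.n_cells_per_group)
            p = config.on_prob_for(tf, g)
            tf_state[sl, ti] = rng.random(config.n_cells_per_group) < p

    # Per-cell mean matrix -------------------------------------------------
    mean = np.tile(base_mean, (n_cells, 1))
    for ti, tf in enumerate(tfs):
        on = tf_state[:, ti].astype(bool)
        mean[on, gene_index[tf]] *= config.beta
        for g in groups:
            in_group = age_group == g
            rows = on & in_group
            if not rows.any():
                continue
            for tg in _responsive_targets(config, tf, g):
                mean[rows, gene_index[tg]] *= config.beta
    is_a = cell_type == "typeA"
    mean[is_a, gene_index[MARKER_A]] = config.marker_high_mean
    mean[~is_a, gene_index[MARKER_B]] = config.marker_high_mean

    libsize = rng.lognormal(*config.libsize_lognormal, size=n_cells)
    mean *= libsize[:, None]

    counts = _nb_draw(rng, mean, config.nb_dispersion).astype(np.int64)

    obs = pd.DataFrame(
        {
            "donor": donors,
            "age": ages,
            "age_group": pd.Categorical(age_group, categories=groups, ordered=True),
            "sex": sex,
            "study": studies,
            "cell_type": cell_type,
            "cell_label": cell_type,
        },
        index=cell_names,
    )
    kind = (
        ["tf" if g in set(tfs) else "target" for g in genes[: config.n_tfs * (1 + config.n_targets_per_tf)]]
        + ["noise"] * config.n_noise_genes
        + ["marker", "marker"]
    )
    var = pd.DataFrame({"kind": kind, "is_mito": False}, index=genes)
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)

    edges = [
        (
            tf,
            tg,
            tuple(g for g in groups if tg in _responsive_targets(config, tf, g)),
        )
        for tf in tfs
        for tg in config.target_names(tf)
    ]
    truth = SyntheticTruth(
        edges=edges,
        tf_state=pd.DataFrame(tf_state, index=cell_names, columns=tfs),
        doublet_flags=pd.Series(False, index=cell_names),
    )

    if config.doublet_rate > 0:
        adata, flags = spike_doublets(adata, config.doublet_rate, seed=int(rng.integers(2**31)))
        # truth rows for spiked cells: TF state taken from the first parent
        parents = adata.uns["doublet_parents"]
        extra_state = truth.tf_state.loc[[p[0] for p in parents]]
        extra_state.index = [c for c, f in flags.items() if f and c not in truth.tf_state.index]
        truth.tf_state = pd.concat([truth.tf_state, extra_state])
        truth.doublet_flags = flags
    return adata, truth


def spike_doublets(
    adata: ad.AnnData, rate: float, seed: int = 0
) -> tuple[ad.AnnData, pd.Series]:
    """Append ``floor(rate * n_cells)`` synthetic doublets to a dataset.

    Each doublet's count vector is the element-wise sum of one randomly
    drawn cell of each of the two simulated cell types; metadata is copied
    from the first parent. Returns the augmented matrix plus per-cell flags.
    """
    if rate >= 1:
        raise ValueError("doublet rate must be < 1")
    flags = pd.Series(False, index=adata.obs_names)
    if rate <= 0:
        return adata, flags
    types = adata.obs["cell_type"]
    idx_a = np.flatnonzero((types == "typeA").to_numpy())
    idx_b = np.flatnonzero((types == "typeB").to_numpy())
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need at least two cells of each simulated type to spike doublets")
    rng = np.random.default_rng(seed)
    n_doublets = int(np.floor(rate * adata.n_obs))
    pa = rng.choice(idx_a, size=n_doublets, replace=True)
    pb = rng.choice(idx_b, size=n_doublets, replace=True)
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    dbl = X[pa] + X[pb]
    names = [f"doublet{i:04d}" for i in range(n_doublets)]
    obs = adata.obs.iloc[pa].copy()
    obs.index = names
    obs["cell_type"] = "doublet"
    extra = ad.AnnData(X=dbl, obs=obs, var=adata.var.copy())
    out = ad.concat([adata, extra], join="outer", merge="same")
    out.var = adata.var.copy()
    out.uns["doublet_parents"] = [
        (adata.obs_names[a], adata.obs_names[b]) for a, b in zip(pa, pb)
    ]
    flags = pd.Series(False, index=out.obs_names)
    flags[names] = True
    return out, flags


def generate_motif_prior(
    truth: SyntheticTruth,
    fpr: float = 0.0,
    fnr: float = 0.0,
    seed: int = 0,
    gene_universe: Sequence[str] | None = None,
    window: str = "500bp-up",
    n_motifs_range: tuple[int, int] = (2, 10),
) -> pd.DataFrame:
    """Derive a noisy motif-prior table from the planted edges.

    Each planted (TF, target) pair enters the prior with probability
    ``1 - fnr``; each non-edge (TF, gene) pair with probability ``fpr``.
    Returns a tidy table with columns ``tf, target, n_motifs, window``.
    """
    if not (0.0 <= fpr < 1.0 and 0.0 <= fnr <= 1.0):
        raise ValueError("fpr must be in [0,1) and fnr in [0,1]")
    rng = np.random.default_rng(seed)
    edge_set = truth.edge_set()
    tfs = sorted({tf for tf, _, _ in truth.edges})
    if gene_universe is None:
        gene_universe = sorted({tg for _, tg, _ in truth.edges})
    n_motifs = {tf: int(rng.integers(n_motifs_range[0], n_motifs_range[1] + 1)) for tf in tfs}
    rows = []
    for tf in tfs:
        for gene in gene_universe:
            if gene == tf:
                continue
            p = (1.0 - fnr) if (tf, gene) in edge_set else fpr
            if rng.random() < p:
                rows.append((tf, gene, n_motifs[tf], window))
    return pd.DataFrame(rows, columns=["tf", "target", "n_motifs", "window"])


def aging_trajectory_scenario(
    seed: int = 0,
    n_cells_per_stage: int = 110,
    n_core: int = 4,
    n_ordering: int = 8,
    n_program: int = 8,
    delta_on: float = 0.6,
) -> tuple[SynthConfig, dict[str, list[str]], "pd.Series"]:
    """Aging-continuum scenario with three planted age-group TF programs.

    Nine fine age stages emulate the continuous aging axis. Three kinds of
    TFs are planted: shared *core* TFs (ON probability 0.5 everywhere),
    *ordering* TFs whose ON probability declines linearly across stages
    (they carry the continuum, as maturation gradients do in real data),
    and three group-specific *programs* of ``n_program`` TFs each that are
    ON with probability ``0.5 + delta_on / 2`` in their own age group and
    ``0.5 - delta_on / 2`` elsewhere (an ON-fraction shift of ``delta_on``).
    Stages 0-2 are labelled infant, 3-5 adult, 6-8 old.

    Returns the configuration, the program membership dict
    (``{"infant": [...], "adult": [...], "old": [...]}``) and a mapping
    from stage label to coarse age-group label.
    """
    stages = [f"s{i}" for i in range(9)]
    main_of = lambda x: "infant" if x <= 2 else ("adult" if x <= 5 else "old")
    n_tf = n_core + n_ordering + 3 * n_program
    tfs = [f"TF{i:03d}" for i in range(1, n_tf + 1)]
    core = tfs[:n_core]
    ordering = tfs[n_core : n_core + n_ordering]
    programs = {
        g: tfs[n_core + n_ordering + n_program * i : n_core + n_ordering + n_program * (i + 1)]
        for i, g in enumerate(("infant", "adult", "old"))
    }
    hi, lo = 0.5 + delta_on / 2, 0.5 - delta_on / 2
    on_prob: dict[str, dict[str, float]] = {}
    for x, st in enumerate(stages):
        g = main_of(x)
        d = {t: 0.5 for t in core}
        d.update({t: 0.9 - 0.1 * x for t in ordering})
        for prog, members in programs.items():
            for t in members:
                d[t] = hi if prog == g else lo
        on_prob[st] = d
    config = SynthConfig(
        n_tfs=n_tf,
        n_targets_per_tf=2,
        n_noise_genes=5,
        n_cells_per_group=n_cells_per_stage,
        age_groups=tuple(stages),
        on_prob=on_prob,
        seed=seed,
    )
    stage_to_group = pd.Series({st: main_of(x) for x, st in enumerate(stages)})
    return config, programs, stage_to_group


def write_dataset(adata: ad.AnnData, truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write MTX counts, TSV gene/cell metadata and JSON truth to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from scipy.io import mmwrite

    X = adata.X.tocoo() if sp.issparse(adata.X) else sp.coo_matrix(adata.X)
    mmwrite(outdir / "counts.mtx", X)
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    (outdir / "truth.json").write_text(truth.to_json())
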