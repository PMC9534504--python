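import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from regudyn import SynthConfig, generate_dataset, generate_motif_prior, normalize_log


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-regulon dataset shared by read-only tests."""
    cfg = SynthConfig(
        n_tfs=5,
        n_targets_per_tf=10,
        n_noise_genes=40,
        n_cells_per_group=120,
        seed=7,
    )
    adata, truth = generate_dataset(cfg)
    normalize_log(adata)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def small_prior(small_dataset):
    cfg, adata, truth = small_dataset
    return generate_motif_prior(truth, fpr=0.0, fnr=0.0, seed=3, gene_universe=list(adata.var_names))


def make_adata(counts, gene_names=None, cell_names=None, obs=None, is_mito=None):
    """Build a minimal AnnData from a dense cells x genes count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_names = gene_names or [f"g{j}" for j in range(n_genes)]
    cell_names = cell_names or [f"c{i}" for i in range(n_cells)]
    var = pd.DataFrame(index=gene_names)
    var["is_mito"] = is_mito if is_mito is not None else False
    if obs is None:
        obs = pd.DataFrame(index=cell_names)
    else:
        obs = obs.copy()
        obs.index = cell_names
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
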