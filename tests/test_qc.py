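"""QC filters, normalization, bimodal thresholds, pseudobulk and markers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from regudyn import (
    SynthConfig,
    bimodal_threshold,
    filter_cells_genes,
    flag_coexpression_doublets,
    generate_dataset,
    normalize_log,
    pseudobulk_group_correlation,
    rank_markers,
)
from regudyn.synth import MARKER_A, MARKER_B

from conftest import make_adata


class TestFilterCellsGenes:
    def test_toy_cells_filtered_by_each_rule(self):
        """Five cells: too few genes, ok, too many, mito-heavy, ok."""
        n_genes = 10000
        counts = np.zeros((5, n_genes))
        for i, d in zip([0, 1, 2, 4], [150, 500, 9000, 700]):
            counts[i, :d] = 1
        # cell 3: 600 detected genes, 200 of them mitochondrial -> mito 33%
        counts[3, :400] = 1
        counts[3, -200:] = 1
        is_mito = np.zeros(n_genes, dtype=bool)
        is_mito[-200:] = True
        adata = make_adata(counts, is_mito=is_mito)
        out, report = filter_cells_genes(adata, min_cells_per_gene=1)
        assert report.n_cells_out == 2
        assert set(out.obs_names) == {"c1", "c4"}
        assert report.removed_low_genes == 1
        assert report.removed_high_genes == 1
        assert report.removed_high_mito == 1

    def test_gene_detected_in_too_few_retained_cells_dropped(self):
        counts = np.array([
            # gene0 in 3 cells, gene1 in 2 cells, gene2 in all
            [1, 1, 1], [1, 1, 1], [1, 0, 1], [0, 0, 1],
        ])
        adata = make_adata(counts)
        out, report = filter_cells_genes(adata, min_genes=1, max_genes=10, min_cells_per_gene=3)
        assert list(out.var_names) == ["g0", "g2"]
        assert report.removed_genes_min_cells == 1

    def test_planted_violation_counts_reported_exactly(self):
        """Cells planted to break exactly one filter each are counted per filter."""
        rng = np.random.default_rng(0)
        n_cells, n_genes = 1000, 300
        counts = np.zeros((n_cells, n_genes), dtype=int)
        for i in range(n_cells):
            genes = rng.choice(np.arange(20, n_genes), size=100, replace=False)
            counts[i, genes] = 1
        is_mito = np.zeros(n_genes, dtype=bool)
        is_mito[:20] = True
        low, high, mito = list(range(12)), list(range(12, 25)), list(range(25, 37))
        for i in low:
            counts[i] = 0
            counts[i, rng.choice(np.arange(20, n_genes), 30, replace=False)] = 1
        for i in high:
            counts[i] = 1
        for i in mito:
            counts[i, :20] = 100  # mito reads dominate
        adata = make_adata(counts, is_mito=is_mito)
        out, report = filter_cells_genes(
            adata, min_genes=50, max_genes=200, max_mito_frac=0.25, min_cells_per_gene=1
        )
        assert report.removed_low_genes == 12
        assert report.removed_high_genes == 13
        assert report.removed_high_mito == 12
        assert report.n_cells_out == 1000 - 37

    def test_idempotent(self, small_dataset):
        _, adata, _ = small_dataset
        once, _ = filter_cells_genes(adata, min_genes=10, max_genes=10**6)
        twice, r2 = filter_cells_genes(once, min_genes=10, max_genes=10**6)
        assert once.shape == twice.shape
        assert r2.n_cells_in == r2.n_cells_out

    def test_all_cells_removed_is_an_error(self):
        adata = make_adata(np.ones((3, 5)))
        with pytest.raises(ValueError, match="all cells removed"):
            filter_cells_genes(adata, min_genes=100)


class TestNormalizeLog:
    def test_closed_form_value(self):
        adata = make_adata(np.array([[1, 1, 2]]))
        normalize_log(adata)
        got = adata.layers["lognorm"].toarray()[0, 2]
        assert got == pytest.approx(np.log(1 + 2 / 4 * 1e4), abs=1e-9)
        assert np.log(5001) == pytest.approx(8.5174, abs=1e-4)

    def test_zero_count_maps_to_zero(self):
        adata = make_adata(np.array([[0, 3]]))
        normalize_log(adata)
        assert adata.layers["lognorm"].toarray()[0, 0] == 0.0

    @pytest.mark.parametrize("factor", [2, 7])
    def test_per_cell_scale_invariance(self, factor):
        counts = np.array([[3, 0, 5, 1], [2, 2, 2, 2]])
        a = make_adata(counts)
        b = make_adata(counts * factor)
        normalize_log(a), normalize_log(b)
        np.testing.assert_allclose(
            a.layers["lognorm"].toarray(), b.layers["lognorm"].toarray(), atol=1e-12
        )

    def test_monotone_within_cell(self):
        adata = make_adata(np.array([[1, 4, 2, 9]]))
        normalize_log(adata)
        vals = adata.layers["lognorm"].toarray()[0]
        assert np.argsort(vals).tolist() == np.argsort([1, 4, 2, 9]).tolist()

    def test_zero_library_cell_named_in_error(self):
        adata = make_adata(np.array([[1, 1], [0, 0]]))
        with pytest.raises(ValueError, match="c1"):
            normalize_log(adata)


class TestBimodalThreshold:
    def test_constant_input_gives_infinity(self):
        with pytest.warns(UserWarning):
            assert np.isinf(bimodal_threshold(np.full(50, 1.3)))

    def test_threshold_lies_between_separated_modes(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0.2, 0.05, 500), rng.normal(2.0, 0.05, 500)])
        t = bimodal_threshold(vals)
        assert 0.5 < t < 1.7

    def test_membership_accuracy_at_six_sigma(self):
        rng = np.random.default_rng(8)
        low = rng.normal(0.0, 0.1, 400)
        high = rng.normal(1.0, 0.1, 400)  # 10 sigma apart -> > 6 sigma
        t = bimodal_threshold(np.concatenate([low, high]))
        acc = ((low <= t).sum() + (high > t).sum()) / 800
        assert acc >= 0.95

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bimodal_threshold(np.arange(10))


class TestDoubletFlagging:
    def test_missing_gene_is_an_error(self, small_dataset):
        _, adata, _ = small_dataset
        with pytest.raises(KeyError):
            flag_coexpression_doublets(adata, "NOPE", MARKER_B)

    def test_recall_of_planted_doublets(self):
        cfg = SynthConfig(
            n_tfs=3, n_targets_per_tf=5, n_noise_genes=30,
            n_cells_per_group=300, doublet_rate=0.05, seed=21,
        )
        adata, truth = generate_dataset(cfg)
        normalize_log(adata)
        flags = flag_coexpression_doublets(adata, MARKER_A, MARKER_B)
        planted = truth.doublet_flags.reindex(adata.obs_names).astype(bool)
        recall = (flags & planted).sum() / planted.sum()
        assert recall >= 0.9

    def test_single_positive_cells_not_flagged(self):
        cfg = SynthConfig(n_tfs=3, n_targets_per_tf=5, n_noise_genes=30,
                          n_cells_per_group=300, doublet_rate=0.05, seed=22)
        adata, truth = generate_dataset(cfg)
        normalize_log(adata)
        flags = flag_coexpression_doublets(adata, MARKER_A, MARKER_B)
        planted = truth.doublet_flags.reindex(adata.obs_names).astype(bool)
        false_rate = (flags & ~planted).sum() / (~planted).sum()
        assert false_rate < 0.05


class TestPseudobulkCorrelation:
    def _with_groups(self, profiles, n_per_group=30, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for name, p in profiles.items():
            for _ in range(n_per_group):
                rows.append(rng.poisson(np.maximum(p + rng.normal(0, noise, len(p)), 0.01) * 20))
                labels.append(name)
        obs = pd.DataFrame({"grp": labels})
        adata = make_adata(np.array(rows), obs=obs)
        normalize_log(adata)
        return adata

    def test_identical_profiles_correlate_perfectly(self):
        p = np.arange(1, 31)
        counts = np.tile(p, (20, 1))  # every cell identical in both groups
        obs = pd.DataFrame({"grp": ["a"] * 10 + ["b"] * 10})
        adata = make_adata(counts, obs=obs)
        normalize_log(adata)
        corr, _ = pseudobulk_group_correlation(adata, "grp")
        assert corr.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)

    def test_anticorrelated_profiles(self):
        x = np.arange(1.0, 21)
        counts = np.vstack([np.tile(x * 5, (6, 1)), np.tile((-x + 21) * 5, (6, 1))]).astype(int)
        obs = pd.DataFrame({"grp": ["a"] * 6 + ["b"] * 6})
        adata = make_adata(counts, obs=obs)
        # compare raw anti-linear profiles without log distortion
        adata.layers["lognorm"] = adata.X.copy().astype(float)
        corr, _ = pseudobulk_group_correlation(adata, "grp")
        assert corr.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_planted_clades_recovered(self):
        """Groups {1,4} and {2,3} share signatures; HCA splits them so."""
        rng = np.random.default_rng(3)
        sig1, sig2 = rng.uniform(1, 6, 40), rng.uniform(1, 6, 40)
        adata = self._with_groups({"g1": sig1, "g2": sig2, "g3": sig2, "g4": sig1}, seed=3)
        corr, order = pseudobulk_group_correlation(adata, "grp")
        Z = hierarchy.linkage(
            hierarchy.distance.squareform(1 - corr.to_numpy(), checks=False), "average"
        )
        cut = hierarchy.fcluster(Z, 2, "maxclust")
        clades = {}
        for name, c in zip(corr.index, cut):
            clades.setdefault(c, set()).add(name)
        assert {frozenset(v) for v in clades.values()} == {
            frozenset({"g1", "g4"}), frozenset({"g2", "g3"}),
        }


class TestRankMarkers:
    @staticmethod
    def exact_ranksum_p(x, y):
        """Enumerate all rank assignments of the pooled sample (no ties)."""
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[: len(x)].sum()
        n = len(pooled)
        sums = [sum(c) for c in itertools.combinations(ranks, len(x))]
        mean = np.mean(sums)
        extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-9)
        return extreme / len(sums)

    def test_exact_p_for_separated_triples(self):
        # second constant gene keeps library sizes uneven so the first
        # gene's normalized values stay distinct across cells
        counts = np.column_stack([np.arange(1, 7) * 10, np.full(6, 100)])
        obs = pd.DataFrame({"cl": ["A"] * 3 + ["B"] * 3})
        adata = make_adata(counts, obs=obs)
        normalize_log(adata)
        table = rank_markers(adata, "cl")
        expected = self.exact_ranksum_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert expected == pytest.approx(0.1)
        assert table["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_gene_has_p_one_and_zero_effect(self):
        # equal library sizes keep the constant gene constant after scaling
        counts = np.column_stack([np.full(8, 5), np.full(8, 10)])
        obs = pd.DataFrame({"cl": ["A"] * 4 + ["B"] * 4})
        adata = make_adata(counts, obs=obs)
        normalize_log(adata)
        table = rank_markers(adata, "cl")
        flat = table[table["gene"] == "g0"]
        assert (flat["p"] == 1.0).all() and (flat["effect"] == 0.0).all()

    def test_planted_markers_recovered_at_fdr(self):
        """20 genes boosted fourfold in one cluster dominate its ranking."""
        rng = np.random.default_rng(5)
        n_genes, n_cells = 120, 160
        base = rng.uniform(1, 4, n_genes)
        labels = np.array(["A"] * 80 + ["B"] * 80)
        mean = np.tile(base, (n_cells, 1))
        mean[labels == "A", :20] *= 4
        counts = rng.poisson(mean * 5)
        adata = make_adata(counts, obs=pd.DataFrame({"cl": labels}))
        normalize_log(adata)
        table = rank_markers(adata, "cl")
        top = table[(table["cluster"] == "A") & (table["p_adj"] < 0.05) & (table["effect"] > 0)]
        planted = {f"g{j}" for j in range(20)}
        assert planted <= set(top["gene"])
        ranked = table[table["cluster"] == "A"]["gene"].tolist()
        assert planted <= set(ranked[:40])

    def test_bh_adjustment_monotone(self, small_dataset):
        _, adata, _ = small_dataset
        labels = pd.Series(
            np.where(np.arange(adata.n_obs) % 2 == 0, "x", "y"), index=adata.obs_names
        )
        adata = adata.copy()
        adata.obs["half"] = labels
        table = rank_markers(adata, "half")
        assert (table["p_adj"] >= table["p"] - 1e-12).all()
        for _, grp in table.groupby("cluster"):
            s = grp.sort_values("p")
            assert s["p_adj"].is_monotonic_increasing or np.allclose(
                s["p_adj"], np.maximum.accumulate(s["p_adj"]), atol=1e-12
            )

    def test_tiny_cluster_skipped(self):
        counts = np.arange(10).reshape(5, 2) + 1
        obs = pd.DataFrame({"cl": ["A", "A", "A", "A", "B"]})
        adata = make_adata(counts, obs=obs)
        normalize_log(adata)
        with pytest.warns(UserWarning, match="fewer than 3"):
            table = rank_markers(adata, "cl")
        assert set(table["cluster"]) == {"A"}
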