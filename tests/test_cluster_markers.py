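"""Normalization, clustering, marker detection, labelling, correlation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from at1screen.cluster_markers import (
    ClusterAssignment,
    embed_and_cluster,
    find_markers,
    gene_correlation,
    label_clusters,
    normalize,
    top_n_markers,
)
from at1screen.io_formats import CountMatrix, GeneSet, RunConfig
from at1screen.synthetic_data import SimSpec, simulate_counts


def _count_matrix(genes, array):
    arr = np.asarray(array)
    return CountMatrix(genes, [f"c{i}" for i in range(arr.shape[1])],
                       sp.csr_matrix(arr))


class TestNormalize:
    def test_cpm_arithmetic(self):
        cm = _count_matrix(["g1", "g2"], [[10], [90]])
        norm = normalize(cm)
        np.testing.assert_allclose(norm.cpm()[:, 0], [100_000, 900_000], rtol=1e-9)

    def test_all_zero_gene_stays_zero(self):
        cm = _count_matrix(["g1", "g2"], [[0, 0], [5, 7]])
        assert np.all(normalize(cm).values[0] == 0)

    def test_scale_invariance_under_count_doubling(self):
        cm1 = _count_matrix(["g1", "g2", "g3"], [[1], [2], [3]])
        cm2 = _count_matrix(["g1", "g2", "g3"], [[2], [4], [6]])
        np.testing.assert_allclose(normalize(cm1).values, normalize(cm2).values)

    def test_library_sizes_recoverable(self):
        cm = _count_matrix(["g1", "g2"], [[3, 0], [4, 0]])
        with pytest.warns(UserWarning):
            norm = normalize(cm)
        np.testing.assert_array_equal(norm.library_sizes, [7, 0])


class TestClustering:
    def test_two_well_separated_clusters_ari_one(self):
        spec = SimSpec(cluster_labels=("AT1", "AT2"), n_cells_per_cluster=25,
                       n_genes=500, n_lowq_cells=0, seed=3)
        cm, truth = simulate_counts(spec)
        cfg = RunConfig(n_hvg=200, k_neighbors=10)
        assignment, _ = embed_and_cluster(normalize(cm), cfg)
        pred = [assignment.cluster_of[c] for c in cm.cells]
        true = [truth.cell_clusters[c] for c in cm.cells]
        assert adjusted_rand_score(true, pred) == 1.0

    def test_identical_cells_form_single_cluster(self):
        cm = _count_matrix([f"g{i}" for i in range(30)],
                           np.tile([[3]] * 30, (1, 20)))
        cfg = RunConfig(n_hvg=30, n_pcs=5, k_neighbors=10)
        assignment, _ = embed_and_cluster(normalize(cm), cfg)
        assert assignment.cluster_ids == [1]

    def test_too_few_cells_for_neighbors_is_error(self):
        cm = _count_matrix(["g1", "g2"], np.ones((2, 5), dtype=int))
        with pytest.raises(ValueError, match="k_neighbors"):
            embed_and_cluster(normalize(cm), RunConfig(k_neighbors=15))

    def test_default_fixture_recovers_six_communities(self, pipeline_result, sim_bundle):
        assignment = pipeline_result.assignment
        assert len(assignment.cluster_ids) == 6
        truth = sim_bundle["truth"]
        cells = pipeline_result.normalized.cells
        ari = adjusted_rand_score(
            [truth.cell_clusters[c] for c in cells],
            [assignment.cluster_of[c] for c in cells],
        )
        assert ari > 0.9

    def test_partition_invariant_to_cell_permutation(self, sim_bundle,
                                                     pipeline_result):
        cells = list(pipeline_result.normalized.cells)
        rng = np.random.default_rng(11)
        permuted = [cells[i] for i in rng.permutation(len(cells))]
        norm_p = normalize(sim_bundle["counts"].subset_cells(permuted))
        assignment_p, _ = embed_and_cluster(norm_p, RunConfig())
        base = [pipeline_result.assignment.cluster_of[c] for c in cells]
        perm = [assignment_p.cluster_of[c] for c in cells]
        assert adjusted_rand_score(base, perm) == 1.0


class TestFindMarkers:
    def _toy_norm(self):
        # 2 genes x 6 cells; first 3 cells form the cluster of interest
        cm = _count_matrix(
            ["up", "flat"],
            [[50, 60, 70, 1, 2, 3], [10, 10, 10, 10, 10, 10]],
        )
        return normalize(cm)

    def _toy_assignment(self):
        return ClusterAssignment({f"c{i}": 1 if i < 3 else 2 for i in range(6)})

    def test_exact_p_for_separated_small_groups(self):
        table = find_markers(self._toy_norm(), self._toy_assignment(), 1)
        row = table[table["gene"] == "up"].iloc[0]
        assert row["p_value"] == pytest.approx(0.1)

    def test_adjusted_p_bounds_and_order(self):
        table = find_markers(self._toy_norm(), self._toy_assignment(), 1)
        assert np.all(table["adjusted_p"] >= table["p_value"] - 1e-12)
        assert np.all(table["adjusted_p"] <= 1.0)
        assert list(table["rank"]) == list(range(1, len(table) + 1))

    def test_degenerate_single_group_rejected(self):
        norm = self._toy_norm()
        assignment = ClusterAssignment({f"c{i}": 1 for i in range(6)})
        with pytest.raises(ValueError, match="non-empty"):
            find_markers(norm, assignment, 1)

    def test_excluded_genes_never_in_table(self):
        table = find_markers(self._toy_norm(), self._toy_assignment(), 1,
                             exclude_genes=("up",))
        assert "up" not in set(table["gene"])

    def test_ranking_invariant_to_gene_row_permutation(self, pipeline_result,
                                                       sim_bundle):
        norm = pipeline_result.normalized
        assignment = pipeline_result.assignment
        target = pipeline_result.target_cluster
        base = find_markers(norm, assignment, target)
        rng = np.random.default_rng(5)
        order = rng.permutation(len(norm.genes))
        cm = sim_bundle["counts"].subset_cells(list(norm.cells))
        shuffled = CountMatrix(
            [cm.genes[i] for i in order], list(cm.cells), cm.counts[order]
        )
        table_p = find_markers(normalize(shuffled), assignment, target)
        assert list(table_p["gene"]) == list(base["gene"])
        np.testing.assert_allclose(
            table_p["adjusted_p"].to_numpy(), base["adjusted_p"].to_numpy()
        )


class TestTopN:
    def _table(self, genes, padj, lfc):
        n = len(genes)
        df = pd.DataFrame(
            {
                "gene": genes, "cluster": 1, "log2_fold_change": lfc,
                "p_value": padj, "adjusted_p": padj,
                "in_cluster_mean": 1.0, "out_cluster_mean": 1.0,
            }
        )
        df = df.sort_values(["adjusted_p", "log2_fold_change", "gene"],
                            ascending=[True, False, True], kind="stable")
        df["rank"] = range(1, n + 1)
        return df

    def test_sort_order_forced_by_ties(self):
        table = self._table(["gene1", "gene2", "gene3"],
                            [0.01, 0.01, 0.2], [1.0, 2.0, 3.0])
        top = top_n_markers(table, 2)
        assert top.canonical() == {"gene1", "gene2"}
        # gene2 outranks gene1: same adjusted p, larger fold change
        assert table.iloc[0]["gene"] == "gene2"

    def test_negative_fold_genes_never_returned(self):
        table = self._table(["a", "b"], [0.01, 0.02], [-1.0, 0.5])
        with pytest.warns(UserWarning):
            top = top_n_markers(table, 2)
        assert top.canonical() == {"b"}

    def test_n_larger_than_table_warns_and_returns_all(self):
        table = self._table(["a", "b"], [0.01, 0.02], [1.0, 0.5])
        with pytest.warns(UserWarning):
            top = top_n_markers(table, 10)
        assert len(top) == 2

    def test_planted_markers_dominate_top_100(self, pipeline_result, sim_bundle):
        table = pipeline_result.marker_tables[pipeline_result.target_cluster]
        top = top_n_markers(table, 100)
        planted = sim_bundle["truth"].markers_of("AT1")
        recovered = sum(1 for g in planted if g in top)
        assert recovered / len(planted) >= 0.9


class TestLabelClusters:
    def _table_for(self, genes):
        n = len(genes)
        return pd.DataFrame(
            {
                "gene": genes, "cluster": 1,
                "log2_fold_change": np.linspace(3, 1, n),
                "p_value": np.linspace(0.001, 0.5, n),
                "adjusted_p": np.linspace(0.001, 0.5, n),
                "in_cluster_mean": np.linspace(100, 10, n),
                "out_cluster_mean": 1.0,
                "rank": range(1, n + 1),
            }
        )

    def test_sftpc_topped_cluster_is_at2(self):
        labels = label_clusters({1: self._table_for(["Sftpc", "Gene1", "Gene2"])})
        assert labels[1] == "AT2"

    def test_no_canonical_marker_expressed_is_unlabeled(self):
        table = self._table_for(["GeneA", "GeneB"])
        assert label_clusters({1: table})[1] == "unlabeled"

    def test_tied_clusters_get_disambiguating_suffix(self):
        t = self._table_for(["Sftpc", "GeneX"])
        labels = label_clusters({1: t, 2: t.assign(cluster=2)})
        assert labels == {1: "AT2-1", 2: "AT2-2"}

    def test_default_fixture_labels_match_planted_cell_types(self, pipeline_result,
                                                             sim_bundle):
        """Each cluster's assigned label equals the planted cell type of the
        majority of its cells (a handful of borderline cells may stray)."""
        assignment = pipeline_result.assignment
        truth = sim_bundle["truth"]
        for k in assignment.cluster_ids:
            cells = assignment.cells_in(k)
            planted = pd.Series([truth.cell_clusters[c] for c in cells])
            assert planted.mode()[0] == assignment.label_of(k)


class TestGeneCorrelation:
    def _norm(self):
        # equal library sizes so per-gene CPM profiles are exactly the counts
        cm = _count_matrix(
            ["a", "b", "pad", "flat"],
            [[1, 2, 3, 4], [1, 2, 3, 4], [8, 6, 4, 2], [5, 5, 5, 5]],
        )
        return normalize(cm)

    def test_identical_profiles_correlate_perfectly(self):
        res = gene_correlation(self._norm(), "a", "b")
        assert res.defined and res.rho == pytest.approx(1.0)

    def test_constant_gene_flagged_undefined(self):
        res = gene_correlation(self._norm(), "a", "flat")
        assert not res.defined

    def test_missing_gene_is_error(self):
        with pytest.raises(KeyError):
            gene_correlation(self._norm(), "a", "nope")

    def test_reporter_tracks_its_driver_in_epithelium(self, pipeline_result):
        """The transgene is driven from the Aqp5 locus: positive correlation."""
        rho, p = pipeline_result.correlations["Aqp5~tdTomato"]
        assert rho > 0 and p < 0.05
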