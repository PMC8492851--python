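"""PCA, SNN-Louvain communities, rank-sum markers, projection label transfer."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from orgstate import cluster, io_qc, synth
from orgstate.errors import ConfigurationError


class TestPCA:
    def test_rank_one_data_explained_by_first_pc(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(80, 1)) @ rng.normal(size=(1, 20))
        model = cluster.pca(base + rng.normal(scale=1e-6, size=base.shape), n_pcs=5)
        assert model.explained_variance_ratio[0] > 0.999

    def test_embeddings_match_dense_eigendecomposition(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 20))
        model = cluster.pca(x, n_pcs=5)
        # independent oracle: eigendecomposition of the covariance matrix
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / len(x)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1][:5]
        oracle = xc @ v[:, order]
        for k in range(5):
            a, b = model.embeddings[:, k], oracle[:, k]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        model = cluster.pca(rng.normal(size=(60, 15)), n_pcs=6)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(6), atol=1e-6)

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 10))
        m1 = cluster.pca(x, n_pcs=4)
        m2 = cluster.pca(x.copy(), n_pcs=4)
        assert np.allclose(m1.loadings, m2.loadings)
        # largest-magnitude loading of each PC is positive
        peaks = m1.loadings[np.abs(m1.loadings).argmax(axis=0), np.arange(4)]
        assert (peaks > 0).all()

    def test_too_many_components_raises(self):
        with pytest.raises(ConfigurationError):
            cluster.pca(np.zeros((5, 3)), n_pcs=10)


def _blobs(n_per, centers, sd=1.0, seed=0, dim=5):
    rng = np.random.default_rng(seed)
    parts = [rng.normal(loc=c, scale=sd, size=(n_per, dim)) for c in centers]
    return np.vstack(parts)


class TestSNNLouvain:
    def test_two_separated_blobs_give_two_clusters(self):
        pcs = _blobs(100, centers=[0.0, 10.0])
        labels = cluster.snn_louvain(pcs, k=20, resolution=0.7, seed=0)
        assert labels.n_clusters == 2
        assert len(set(labels.labels[:100])) == 1
        assert len(set(labels.labels[100:])) == 1

    def test_single_blob_low_resolution_one_cluster(self):
        pcs = _blobs(200, centers=[0.0])
        labels = cluster.snn_louvain(pcs, k=20, resolution=0.1, seed=0)
        assert labels.n_clusters == 1

    def test_seeded_determinism(self):
        pcs = _blobs(80, centers=[0.0, 6.0, 12.0])
        a = cluster.snn_louvain(pcs, k=15, resolution=0.7, seed=1)
        b = cluster.snn_louvain(pcs, k=15, resolution=0.7, seed=1)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_contiguous_largest_first(self):
        pcs = _blobs(60, centers=[0.0, 8.0, 16.0])
        labels = cluster.snn_louvain(np.vstack([pcs, pcs[:20]]), k=10, seed=0)
        sizes = np.bincount(labels.labels)
        assert sorted(sizes, reverse=True) == list(sizes)
        assert set(labels.labels) == set(range(labels.n_clusters))

    def test_k_not_smaller_than_n_raises(self):
        with pytest.raises(ConfigurationError):
            cluster.snn_louvain(np.zeros((10, 3)), k=10)

    def test_partition_beats_trivial_modularity(self):
        import igraph
        import scipy.sparse as spp

        pcs = _blobs(100, centers=[0.0, 10.0])
        labels = cluster.snn_louvain(pcs, k=20, resolution=0.7, seed=0)
        snn = cluster._snn_graph(pcs, k=20)
        coo = spp.triu(snn, k=1).tocoo()
        g = igraph.Graph(
            n=len(pcs), edges=list(zip(coo.row, coo.col)), edge_attrs={"weight": coo.data}
        )
        q_found = g.modularity(labels.labels, weights="weight")
        q_trivial = g.modularity([0] * len(pcs), weights="weight")
        assert q_found >= q_trivial


def _shifted_toy():
    """6 + 6 cells; gene 0 shifted by +5 in cluster A."""
    rng = np.random.default_rng(5)
    values = rng.normal(loc=1.0, scale=0.1, size=(12, 5)).clip(min=0)
    values[:6, 0] += 5.0
    adata = ad.AnnData(X=sp.csr_matrix(values))
    adata.var_names = [f"g{i}" for i in range(5)]
    return adata, np.array([0] * 6 + [1] * 6)


class TestWilcoxonMarkers:
    def test_shifted_gene_ranks_first_and_statistic_matches_hand_count(self):
        nm, labels = _shifted_toy()
        table = cluster.wilcoxon_markers(nm, labels)
        top = table[table["cluster"] == 0].iloc[0]
        assert top["gene"] == "g0"
        # by hand: every cluster-A value exceeds every rest value, so the
        # Mann-Whitney U statistic is n1*n2 = 36
        assert top["statistic"] == pytest.approx(36.0)

    def test_identical_distributions_give_no_markers(self):
        rng = np.random.default_rng(0)
        values = rng.normal(1.0, 0.2, size=(40, 30)).clip(min=0)
        nm = ad.AnnData(X=sp.csr_matrix(values))
        labels = np.array([0] * 20 + [1] * 20)
        table = cluster.wilcoxon_markers(nm, labels)
        assert (table["p_adj"] < 0.05).sum() == 0
        assert table["p_adj"].median() > 0.5

    def test_pct_in_out_are_nonzero_fractions(self):
        values = np.zeros((6, 2))
        values[:3, 0] = [1.0, 2.0, 0.0]  # 2/3 of cluster 0
        values[3:, 0] = [1.0, 0.0, 0.0]  # 1/3 of cluster 1
        values[:, 1] = 1.0
        nm = ad.AnnData(X=sp.csr_matrix(values))
        table = cluster.wilcoxon_markers(nm, np.array([0, 0, 0, 1, 1, 1]), min_pct=0.0)
        row = table[(table["cluster"] == 0) & (table["gene"] == "0")].iloc[0]
        assert row["pct_in"] == pytest.approx(2 / 3)
        assert row["pct_out"] == pytest.approx(1 / 3)

    def test_tiny_cluster_skipped_with_warning(self):
        nm, _ = _shifted_toy()
        labels = np.array([0] * 10 + [1] * 2)
        with pytest.warns(UserWarning, match="fewer than 3"):
            table = cluster.wilcoxon_markers(nm, labels)
        assert set(table["cluster"]) == {0}

    def test_type_one_error_controlled_under_permutation(self, small_cohort):
        adata, _ = small_cohort
        nm = io_qc.lognormalize(adata.copy())
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            labels = rng.integers(0, 2, size=nm.n_obs)
            table = cluster.wilcoxon_markers(nm, labels)
            fracs.append((table["p_adj"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05


class TestPatientGenes:
    def test_pct_filters_applied(self):
        # gene 0: 30% in-sample / 95% out  -> excluded by max_pct_out
        # gene 1: 24% in-sample            -> excluded by min_pct_in
        # gene 2: 80% in / 10% out         -> selected
        n = 100
        values = np.zeros((2 * n, 3))
        values[:30, 0] = 1.0
        values[n : n + 95, 0] = 1.0
        values[:24, 1] = 1.0
        values[:80, 2] = 1.0
        values[n : n + 10, 2] = 1.0
        nm = ad.AnnData(X=sp.csr_matrix(values))
        nm.var_names = ["out_too_common", "in_too_rare", "private"]
        labels = np.array(["A"] * n + ["B"] * n)
        result = cluster.patient_specific_genes(nm, labels)
        assert list(result["A"]["gene"]) == ["private"]

    def test_line_private_gene_detected_in_cohort(self):
        cfg = synth.CohortConfig(
            n_lines=2, cells_per_line=150, n_genes=600,
            amp_line_private=3.5, line_private_baseline=0.02,
        )
        adata, _ = synth.generate_cohort(cfg, seed=11)
        nm = io_qc.lognormalize(adata)
        result = cluster.patient_specific_genes(nm, nm.obs["line_id"].to_numpy())
        for line_idx, line in enumerate(sorted(result)):
            private = {f"LIN{line_idx:02d}-{j + 1:02d}" for j in range(4)}
            assert private & set(result[line]["gene"])


class TestProjectAndTransfer:
    def test_reference_projects_onto_itself(self, processed_cohort):
        pm = processed_cohort.pca
        nm = processed_cohort.nm
        mask = nm.var["highly_variable"].to_numpy()
        query = nm[:50, mask].copy()
        emb, table = cluster.project_and_transfer(
            pm, np.zeros(pm.embeddings.shape[0], dtype=int), query
        )
        assert np.allclose(emb, pm.embeddings[:50, :50], atol=1e-8)

    def test_duplicated_cell_gets_own_label_with_full_confidence(self):
        rng = np.random.default_rng(0)
        x = np.vstack(
            [rng.normal(0, 1, size=(60, 30)), rng.normal(8, 1, size=(60, 30))]
        ).clip(min=0)
        scaled = io_qc.ScaledMatrix(
            values=(x - x.mean(0)) / x.std(0),
            gene_names=np.array([f"g{i}" for i in range(30)]),
            means=x.mean(0),
            stds=x.std(0),
            cell_names=np.array([f"c{i}" for i in range(120)]),
        )
        pm = cluster.pca(scaled, n_pcs=10)
        ref_labels = np.array([0] * 60 + [1] * 60)
        query = ad.AnnData(X=sp.csr_matrix(x[:5]))
        query.var_names = scaled.gene_names
        emb, table = cluster.project_and_transfer(pm, ref_labels, query, k=20)
        assert (table["label"] == 0).all()
        assert (table["confidence"] == 1.0).all()

    def test_k_one_takes_nearest_neighbor_label(self, processed_cohort):
        pm = processed_cohort.pca
        nm = processed_cohort.nm
        mask = nm.var["highly_variable"].to_numpy()
        query = nm[:10, mask].copy()
        labels = np.arange(pm.embeddings.shape[0])  # unique label per ref cell
        _, table = cluster.project_and_transfer(pm, labels, query, k=1)
        assert list(table["label"]) == list(range(10))

    def test_insufficient_gene_overlap_raises(self, processed_cohort):
        pm = processed_cohort.pca
        nm = processed_cohort.nm
        mask = nm.var["highly_variable"].to_numpy()
        query = nm[:5, mask].copy()
        query = query[:, : query.n_vars // 3].copy()
        with pytest.raises(ConfigurationError, match="reference genes"):
            cluster.project_and_transfer(pm, np.zeros(pm.embeddings.shape[0], int), query)
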