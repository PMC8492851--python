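"""PCA, shared-nearest-neighbor Louvain clustering, marker genes, label transfer.

Clustering follows the standard single-cell recipe: a kNN graph in PC space
(k = 20), shared-nearest-neighbor Jaccard edge weights pruned below 1/15, and
Louvain-objective community detection at a configurable resolution (0.7 for
the joint cohort analysis, 0.5 within single organoid lines).  Cross-sample
integration is reference-projection based: query cells are scaled with the
reference gene statistics, projected onto the reference PCA (first 50 PCs)
and labeled by kNN majority vote among reference cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .io_qc import ScaledMatrix

__all__ = [
    "PcaModel",
    "pca",
    "ClusterLabels",
    "snn_louvain",
    "wilcoxon_markers",
    "patient_specific_genes",
    "project_and_transfer",
]

SNN_PRUNE = 1.0 / 15.0


@dataclass
class PcaModel:
    """A fitted PCA with the gene statistics needed to project new data."""

    loadings: np.ndarray  # genes x PCs, orthonormal columns
    embeddings: np.ndarray  # cells x PCs
    explained_variance_ratio: np.ndarray
    gene_names: np.ndarray
    gene_means: np.ndarray  # statistics of the scaling that produced the input
    gene_stds: np.ndarray
    center: np.ndarray  # per-gene mean of the scaled input removed before SVD

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]


def pca(scaled: ScaledMatrix | np.ndarray, n_pcs: int = 50) -> PcaModel:
    """PCA of scaled HVG expression with a fixed sign convention.

    Signs are chosen so that each component's largest-magnitude loading is
    positive, making reruns reproducible.
    """
    if isinstance(scaled, ScaledMatrix):
        values = scaled.values
        gene_names, means, stds = scaled.gene_names, scaled.means, scaled.stds
    else:
        values = np.asarray(scaled, dtype=np.float64)
        gene_names = np.array([f"g{i}" for i in range(values.shape[1])])
        means = np.zeros(values.shape[1])
        stds = np.ones(values.shape[1])
    if n_pcs > min(values.shape):
        raise ConfigurationError(
            f"n_pcs={n_pcs} exceeds min(cells, genes)={min(values.shape)}"
        )
    model = _SKPCA(n_components=n_pcs, svd_solver="full" if min(values.shape) < 1000 else "randomized",
                   random_state=0)
    model.fit(values)
    load = model.components_.T  # genes x PCs
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    load *= flip
    # embeddings defined as the explicit projection, so projecting the same
    # data later reproduces them exactly
    emb = (values - model.mean_) @ load
    return PcaModel(
        loadings=load,
        embeddings=emb,
        explained_variance_ratio=model.explained_variance_ratio_,
        gene_names=np.asarray(gene_names),
        gene_means=np.asarray(means, dtype=float),
        gene_stds=np.asarray(stds, dtype=float),
        center=model.mean_,
    )


@dataclass
class ClusterLabels:
    """Community labels (contiguous from 0, largest community first)."""

    labels: np.ndarray
    resolution: float
    k: int

    def __len__(self):
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _snn_graph(pcs: np.ndarray, k: int, prune: float = SNN_PRUNE) -> sp.csr_matrix:
    """Shared-nearest-neighbor Jaccard graph over a kNN graph (self included)."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # includes self as first neighbor
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # counts of shared neighbors
    shared = shared.tocoo()
    jac = shared.data / (2.0 * k - shared.data)
    keep = jac >= prune
    snn = sp.csr_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    snn.setdiag(0)
    snn.eliminate_zeros()
    return snn


def snn_louvain(
    pcs: np.ndarray, k: int = 20, resolution: float = 0.7, seed: int = 0
) -> ClusterLabels:
    """Louvain-objective community detection on the SNN graph.

    Modularity with a resolution parameter (RBConfiguration quality) optimized
    by leidenalg, seeded for determinism.  Labels are relabeled contiguously by
    decreasing community size.
    """
    pcs = np.asarray(pcs, dtype=np.float64)
    n = pcs.shape[0]
    if k >= n:
        raise ConfigurationError(f"k={k} must be smaller than the number of cells ({n})")
    snn = _snn_graph(pcs, k)
    coo = sp.triu(snn, k=1).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), edge_attrs={"weight": coo.data.tolist()}
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    order = np.argsort([-np.sum(raw == c) for c in range(raw.max() + 1)], kind="stable")
    remap = np.empty(raw.max() + 1, dtype=np.int64)
    remap[order] = np.arange(raw.max() + 1)
    return ClusterLabels(labels=remap[raw], resolution=resolution, k=k)


def _group_stats(X: np.ndarray, in_mask: np.ndarray):
    xin, xout = X[in_mask], X[~in_mask]
    pct_in = (xin > 0).mean(axis=0)
    pct_out = (xout > 0).mean(axis=0)
    effect = xin.mean(axis=0) - xout.mean(axis=0)
    return xin, xout, pct_in, pct_out, effect


def _rank_sum_table(
    X: np.ndarray, gene_names, in_mask: np.ndarray, min_pct: float
) -> pd.DataFrame:
    xin, xout, pct_in, pct_out, effect = _group_stats(X, in_mask)
    test = (pct_in >= min_pct) | (pct_out >= min_pct)
    cols = np.flatnonzero(test)
    if cols.size == 0:
        return pd.DataFrame(
            columns=["gene", "effect", "p", "p_adj", "pct_in", "pct_out", "statistic"]
        )
    res = stats.mannwhitneyu(xin[:, cols], xout[:, cols], alternative="two-sided", axis=0)
    p_adj = multipletests(res.pvalue, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": np.asarray(gene_names)[cols],
            "effect": effect[cols],
            "p": res.pvalue,
            "p_adj": p_adj,
            "pct_in": pct_in[cols],
            "pct_out": pct_out[cols],
            "statistic": res.statistic,
        }
    )
    return table.sort_values(["p_adj", "effect"], ascending=[True, False], kind="stable").reset_index(
        drop=True
    )


def wilcoxon_markers(
    nm: ad.AnnData,
    clusters: ClusterLabels | np.ndarray,
    min_pct: float = 0.1,
    top_n: int | None = None,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker genes per cluster.

    Genes are tested when detected in at least ``min_pct`` of either group;
    p-values are Benjamini-Hochberg adjusted within each cluster and the table
    is sorted by adjusted p, then effect (difference of mean log expression).
    """
    labels = clusters.labels if isinstance(clusters, ClusterLabels) else np.asarray(clusters)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ConfigurationError("need at least two clusters for marker detection")
    X = np.asarray(sp.csr_matrix(nm.X).todense(), dtype=np.float64)
    out = []
    for c in uniq:
        in_mask = labels == c
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; skipped")
            continue
        table = _rank_sum_table(X, nm.var_names, in_mask, min_pct)
        table.insert(0, "cluster", c)
        if top_n is not None:
            table = table.head(top_n)
        out.append(table)
    if not out:
        raise ConfigurationError("no cluster was large enough to test")
    return pd.concat(out, ignore_index=True)


def patient_specific_genes(
    nm: ad.AnnData,
    sample_labels,
    top_n: int = 20,
    min_pct_in: float = 0.25,
    max_pct_out: float = 0.90,
) -> dict[str, pd.DataFrame]:
    """Top enriched genes per sample under expression-fraction filters.

    One-vs-rest rank-sum per sample; genes must be expressed in at least
    ``min_pct_in`` of the sample's cells and at most ``max_pct_out`` of all
    other cells; the ``top_n`` positively enriched genes by effect are kept.
    """
    labels = np.asarray(sample_labels)
    samples = np.unique(labels)
    if samples.size < 2:
        raise ConfigurationError("need at least two samples")
    X = np.asarray(sp.csr_matrix(nm.X).todense(), dtype=np.float64)
    result = {}
    for s in samples:
        in_mask = labels == s
        if in_mask.sum() < 3:
            warnings.warn(f"sample {s!r} has fewer than 3 cells; skipped")
            continue
        table = _rank_sum_table(X, nm.var_names, in_mask, min_pct=0.0)
        table = table[
            (table["pct_in"] >= min_pct_in)
            & (table["pct_out"] <= max_pct_out)
            & (table["effect"] > 0)
        ]
        result[s] = (
            table.sort_values("effect", ascending=False, kind="stable")
            .head(top_n)
            .reset_index(drop=True)
        )
    return result


def project_and_transfer(
    ref: PcaModel,
    ref_labels: ClusterLabels | np.ndarray,
    query: ad.AnnData,
    n_pcs: int = 50,
    k: int = 20,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Project query cells onto a reference PCA and transfer labels by kNN vote.

    Query expression (log-normalized) is restricted to the reference genes,
    scaled with the reference means/SDs, projected with the reference
    loadings, and each query cell takes the majority label among its ``k``
    nearest reference cells in PC space; the vote fraction is the confidence
    and ties break toward the single nearest neighbor.
    """
    labels = ref_labels.labels if isinstance(ref_labels, ClusterLabels) else np.asarray(ref_labels)
    n_pcs = min(n_pcs, ref.n_pcs)
    shared = pd.Index(ref.gene_names).intersection(query.var_names)
    if len(shared) < 0.5 * len(ref.gene_names):
        raise ConfigurationError(
            f"only {len(shared)}/{len(ref.gene_names)} reference genes present in query"
        )
    ref_pos = pd.Index(ref.gene_names).get_indexer(shared)
    q_pos = pd.Index(query.var_names).get_indexer(shared)

    Xq = np.asarray(sp.csr_matrix(query.X)[:, q_pos].todense(), dtype=np.float64)
    stds = np.where(ref.gene_stds[ref_pos] == 0, 1.0, ref.gene_stds[ref_pos])
    Xq = np.clip((Xq - ref.gene_means[ref_pos]) / stds, -10, 10)
    Xq -= ref.center[ref_pos]
    emb = Xq @ ref.loadings[ref_pos, :n_pcs]

    nn = NearestNeighbors(n_neighbors=k).fit(ref.embeddings[:, :n_pcs])
    _, idx = nn.kneighbors(emb)
    votes = labels[idx]
    out = []
    for row in votes:
        vals, counts = np.unique(row, return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        if winners.size == 1:
            lab = winners[0]
        else:  # tie: the nearest reference cell carrying a tied label decides
            lab = next(r for r in row if r in winners)
        out.append((lab, best / k))
    table = pd.DataFrame(out, columns=["label", "confidence"], index=query.obs_names)
    return emb, table
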