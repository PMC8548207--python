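"""Normalization, HVG selection, PCA embedding, kNN graph, community detection.

The latent space is a centered PCA on highly variable genes (50 components by
default).  The embedding is a pluggable interface: anything that produces a
nuclei x d matrix can be fed to :func:`knn_graph`.  Community detection is
modularity optimisation with a resolution parameter (configuration null
model), used both for QC overclustering (resolution 2.0) and the final
cell-type map (resolution 0.85).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

import igraph as ig
import leidenalg

from .core_io import CountMatrix


@dataclass
class LatentEmbedding:
    """Nuclei x d coordinates plus the variance-explained profile."""

    coords: np.ndarray
    variance_ratio: np.ndarray

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborGraph:
    """Symmetric weighted kNN adjacency over nuclei."""

    adjacency: sp.csr_matrix
    k: int
    metric: str

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class ClusterLabels:
    labels: np.ndarray
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def __len__(self) -> int:
        return len(self.labels)


def normalize_log1p(cm: CountMatrix, scale_total: float = 1e4) -> sp.csr_matrix:
    """Counts-per-``scale_total`` log1p normalization, genes x nuclei.

    x_gi = ln(1 + scale_total * c_gi / total_i).
    """
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = cm.nuclei["barcode"].iloc[int(np.argmin(totals))]
        raise ValueError(f"nucleus {bad!r} has zero total counts")
    x = cm.counts.astype(float).tocsc()
    x = x.multiply(scale_total / totals[None, :]).tocsr()
    x.data = np.log1p(x.data)
    return x


def select_hvg(cm: CountMatrix, n_hvg: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Top ``n_hvg`` genes by variance of clipped standardized counts.

    A vst-style criterion: the mean-variance trend is estimated by the
    binned median of log variance against log mean (a loess-free stand-in),
    counts are standardized by the trend sd and clipped at sqrt(n), and
    genes are ranked by the variance of the clipped values.  Computed on
    all nuclei pooled.
    """
    n_genes = cm.n_genes
    if n_hvg > n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds n_genes={n_genes}")
    X = cm.counts.astype(float)
    n = cm.n_nuclei
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)

    expressed = mean > 0
    trend_var = np.full(n_genes, np.nan)
    logm = np.where(expressed, np.log10(np.maximum(mean, 1e-12)), 0.0)
    # binned median of log10 variance vs log10 mean
    order = np.argsort(logm[expressed])
    exp_idx = np.flatnonzero(expressed)[order]
    bins = np.array_split(exp_idx, min(n_bins, exp_idx.size))
    for b in bins:
        positive = var[b] > 0
        med = np.median(np.log10(var[b][positive])) if positive.any() else -12.0
        trend_var[b] = 10.0**med
    trend_sd = np.sqrt(np.maximum(trend_var, 1e-12))

    clip = np.sqrt(n)
    score = np.zeros(n_genes)
    Xcsr = X.tocsr()
    for g in np.flatnonzero(expressed):
        row = Xcsr.getrow(g)
        z_nz = np.clip((row.data - mean[g]) / trend_sd[g], -clip, clip)
        z_zero = np.clip((0.0 - mean[g]) / trend_sd[g], -clip, clip)
        n_zero = n - row.nnz
        s1 = z_nz.sum() + z_zero * n_zero
        s2 = (z_nz**2).sum() + z_zero**2 * n_zero
        score[g] = (s2 - s1**2 / n) / max(n - 1, 1)
    # stable top-n: score descending, gene index ascending on ties
    order = np.lexsort((np.arange(n_genes), -score))
    return np.sort(order[:n_hvg])


def pca_latent(x: np.ndarray | sp.spmatrix, d: int = 50) -> LatentEmbedding:
    """Centered PCA of a nuclei x genes matrix via truncated SVD.

    Sign convention: each component's largest-magnitude loading is positive,
    so repeated runs are identical.
    """
    if sp.issparse(x):
        x = np.asarray(x.todense())
    x = np.asarray(x, dtype=float)
    if d > min(x.shape):
        raise ValueError(f"d={d} exceeds min(matrix dims)={min(x.shape)}")
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(x)
    # deterministic sign: flip so the max-|loading| entry of each PC is positive
    for j in range(d):
        load = pca.components_[j]
        i = int(np.argmax(np.abs(load)))
        if load[i] < 0:
            coords[:, j] *= -1.0
    return LatentEmbedding(coords=coords, variance_ratio=pca.explained_variance_ratio_)


def knn_graph(emb: LatentEmbedding | np.ndarray, k: int = 15, metric: str = "cosine") -> NeighborGraph:
    """Exact k-nearest-neighbor graph, symmetrized by union.

    Cosine distance d in [0, 2] maps to edge weight 1 - d/2 in (0, 1];
    ties broken by lower index (enforced via stable ordering on (distance,
    index)).  Zero vectors are rejected: cosine distance is undefined there.
    """
    coords = emb.coords if isinstance(emb, LatentEmbedding) else np.asarray(emb, float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of nuclei {n}")
    if metric == "cosine":
        norms = np.linalg.norm(coords, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero vector encountered; cosine distance undefined")
    nn = NearestNeighbors(n_neighbors=n if n <= k + 1 else k + 1, metric=metric, algorithm="brute")
    nn.fit(coords)
    dist, idx = nn.kneighbors(coords)
    rows, cols, vals = [], [], []
    for i in range(n):
        # drop self, order ties by (distance, index), take k
        cand = [(dist[i, j], idx[i, j]) for j in range(idx.shape[1]) if idx[i, j] != i]
        cand.sort()
        for d_ij, j in cand[:k]:
            if metric == "cosine":
                w = 1.0 - d_ij / 2.0
            else:
                w = 1.0 / (1.0 + d_ij)
            rows.append(i)
            cols.append(int(j))
            vals.append(max(w, 1e-12))
    adj = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)  # union symmetrization
    return NeighborGraph(adjacency=adj, k=k, metric=metric)


def _graph_from_adjacency(adj: sp.spmatrix) -> ig.Graph:
    coo = sp.triu(adj, k=1).tocoo()
    g = ig.Graph(n=adj.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    g.es["weight"] = coo.data.tolist()
    return g


def louvain_communities(g: NeighborGraph | sp.spmatrix, resolution: float = 1.0, seed: int = 0) -> ClusterLabels:
    """Modularity-based community detection with a resolution parameter.

    Multi-level greedy optimisation of the configuration-null-model quality
    function (RB modularity) with node-order randomisation controlled by
    ``seed``; disconnected components are handled independently by the
    optimiser.  Labels are relabelled contiguously 0..K-1 by first
    occurrence.
    """
    adj = g.adjacency if isinstance(g, NeighborGraph) else sp.csr_matrix(g)
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    graph = _graph_from_adjacency(adj)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if graph.ecount() else None,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    return ClusterLabels(labels=_relabel_contiguous(labels), resolution=resolution)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def modularity(adj: sp.spmatrix, labels: np.ndarray, resolution: float = 1.0) -> float:
    """RB modularity of a partition under the configuration null model."""
    adj = sp.csr_matrix(adj)
    m2 = adj.sum()  # 2m for symmetric adjacency
    if m2 == 0:
        return 0.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    q = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        within = adj[np.ix_(idx, idx)].sum()
        q += within / m2 - resolution * (deg[idx].sum() / m2) ** 2
    return float(q)


def doublet_scores(
    cm: CountMatrix,
    seed: int = 0,
    n_sim_factor: float = 1.0,
    n_hvg: int = 1000,
    d: int = 30,
    k: int = 15,
) -> np.ndarray:
    """Simulate-and-score doublet detection.

    ``n_sim_factor * n`` artificial doublets are formed as count-sums of
    random nucleus pairs, co-embedded with the observed nuclei (log1p
    normalisation, HVGs, PCA), and each observed nucleus is scored by the
    fraction of its k nearest neighbours that are simulated doublets.
    """
    n = cm.n_nuclei
    if n < 50:
        raise ValueError("need at least 50 nuclei for doublet scoring")
    rng = np.random.default_rng(seed)
    n_sim = max(int(round(n_sim_factor * n)), 1)
    pairs = rng.integers(0, n, size=(n_sim, 2))
    counts = cm.counts.tocsc()
    sim = counts[:, pairs[:, 0]] + counts[:, pairs[:, 1]]

    combined = sp.hstack([cm.counts, sim], format="csr")
    totals = np.asarray(combined.sum(axis=0)).ravel()
    norm = combined.astype(float).multiply(1e4 / totals[None, :]).tocsr()
    norm.data = np.log1p(norm.data)

    # HVGs on the observed nuclei only
    hvg = select_hvg(cm, n_hvg=min(n_hvg, cm.n_genes))
    mat = np.asarray(norm[hvg, :].T.todense())
    emb = pca_latent(mat, d=min(d, min(mat.shape)))
    coords = emb.coords

    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric="euclidean")
    nn.fit(coords)
    _, idx = nn.kneighbors(coords[:n])
    scores = np.empty(n)
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        scores[i] = float(np.mean([j >= n for j in neigh]))
    return scores


def flag_doublet_clusters(labels: ClusterLabels | np.ndarray, scores: np.ndarray) -> list[int]:
    """Clusters whose median doublet score exceeds Q3 + 1.5 IQR of medians."""
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    medians = np.array([np.median(scores[lab == c]) for c in uniq])
    q1, q3 = np.percentile(medians, [25, 75])
    bound = q3 + 1.5 * (q3 - q1)
    return [int(c) for c, m in zip(uniq, medians) if m > bound]
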