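"""Embedding, kNN graph, community detection and doublet handling."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from evmap.embed_cluster import (
    ClusterLabels,
    doublet_scores,
    flag_doublet_clusters,
    knn_graph,
    louvain_communities,
    modularity,
    normalize_log1p,
    pca_latent,
    select_hvg,
)
from evmap.synthetic import SimConfig, simulate_experiment
from tests.test_qc import _cm


class TestNormalize:
    def test_closed_form(self):
        cm = _cm([[1], [1]])
        x = normalize_log1p(cm, scale_total=1e4)
        np.testing.assert_allclose(
            np.asarray(x.todense()).ravel(), np.log(5001.0), rtol=1e-12
        )

    def test_zeros_stay_zero(self, rng):
        cm = _cm(rng.poisson(0.5, (20, 10)) + np.eye(20, 10, dtype=int))
        x = np.asarray(normalize_log1p(cm).todense())
        dense = np.asarray(cm.counts.todense())
        assert np.all((dense == 0) == (x == 0))

    def test_identity_scaling(self):
        cm = _cm([[2], [3]])
        x = normalize_log1p(cm, scale_total=5)  # scale equals the column total
        np.testing.assert_allclose(
            np.asarray(x.todense()).ravel(), np.log1p([2, 3]), rtol=1e-12
        )


class TestSelectHVG:
    def test_constant_gene_never_selected(self, rng):
        dense = rng.poisson(3.0, (50, 40))
        dense[7, :] = 5  # constant
        cm = _cm(dense)
        assert 7 not in select_hvg(cm, n_hvg=25)

    def test_planted_high_variance_genes_found(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(2.0, (2000, 150))
        planted = rng.choice(2000, 20, replace=False)
        # bimodal high-fold expression: huge variance at similar mean
        on = rng.random((20, 150)) < 0.5
        dense[planted] = np.where(on, rng.poisson(20.0, (20, 150)), 0)
        cm = _cm(dense)
        top = set(select_hvg(cm, n_hvg=100))
        assert set(planted) <= top

    def test_identity_when_all_requested(self, rng):
        cm = _cm(rng.poisson(2.0, (30, 20)) + 1)
        assert list(select_hvg(cm, n_hvg=30)) == list(range(30))
        with pytest.raises(ValueError):
            select_hvg(cm, n_hvg=31)


class TestPCA:
    def test_exact_rank_two(self, rng):
        u = rng.normal(size=(40, 2))
        v = rng.normal(size=(2, 10))
        emb = pca_latent(u @ v, d=2)
        assert emb.variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_dense_eigendecomposition(self, rng):
        x = rng.normal(size=(10, 6))
        emb = pca_latent(x, d=3)
        xc = x - x.mean(axis=0)
        w = np.linalg.eigvalsh(np.cov(xc.T))[::-1]
        np.testing.assert_allclose(
            emb.variance_ratio[:3], w[:3] / w.sum(), rtol=1e-8
        )
        # coordinate magnitudes match regardless of sign convention
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        np.testing.assert_allclose(np.abs(emb.coords), np.abs(xc @ vt[:3].T), atol=1e-8)

    def test_repeated_runs_identical(self, rng):
        x = rng.normal(size=(30, 8))
        e1, e2 = pca_latent(x, d=4), pca_latent(x, d=4)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_d_too_large(self, rng):
        with pytest.raises(ValueError):
            pca_latent(rng.normal(size=(5, 3)), d=4)


class TestKNNGraph:
    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            knn_graph(rng.normal(size=(5, 2)), k=5)

    def test_matches_brute_force_cosine(self, rng):
        pts = rng.normal(size=(12, 3))
        g = knn_graph(pts, k=4)
        # brute force: cosine distance all pairs
        unit = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        dist = 1 - unit @ unit.T
        for i in range(12):
            order = sorted((dist[i, j], j) for j in range(12) if j != i)
            expect = {j for _, j in order[:4]}
            got = set(g.adjacency[i].indices) | {
                j for j in range(12) if g.adjacency[j, i] and i in set(
                    np.flatnonzero(np.asarray(g.adjacency[j].todense()).ravel()))
            }
            # out-neighbors of i must be within the graph's edges of i
            assert expect <= set(np.flatnonzero(np.asarray(g.adjacency[i].todense()).ravel()))

    def test_duplicated_points_mutual_neighbors(self, rng):
        pts = rng.normal(size=(8, 3))
        pts[1] = pts[0]
        g = knn_graph(pts, k=2)
        assert g.adjacency[0, 1] > 0 and g.adjacency[1, 0] > 0

    def test_no_self_loops_and_weights_in_range(self, rng):
        g = knn_graph(rng.normal(size=(20, 4)), k=3)
        assert g.adjacency.diagonal().sum() == 0
        assert np.all(g.adjacency.data > 0) and np.all(g.adjacency.data <= 1)

    def test_zero_vector_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="cosine"):
            knn_graph(pts, k=1)


def _all_partitions(n):
    """Enumerate set partitions of range(n) as label arrays."""
    if n == 0:
        yield np.array([], dtype=int)
        return
    labels = np.zeros(n, dtype=int)

    def rec(i, k):
        if i == n:
            yield labels.copy()
            return
        for lab in range(k + 1):
            labels[i] = lab
            yield from rec(i + 1, max(k, lab + 1))

    yield from rec(1, 1)


def _toy_graphs():
    # adjacency matrices of small graphs with known community structure
    def clique(n):
        a = np.ones((n, n)) - np.eye(n)
        return a

    two_cliques = np.zeros((8, 8))
    two_cliques[:4, :4] = clique(4)
    two_cliques[4:, 4:] = clique(4)
    barbell = two_cliques.copy()
    barbell[3, 4] = barbell[4, 3] = 1.0
    path7 = np.zeros((7, 7))
    for i in range(6):
        path7[i, i + 1] = path7[i + 1, i] = 1.0
    rng = np.random.default_rng(5)
    rand8 = (rng.random((8, 8)) < 0.4).astype(float)
    rand8 = np.triu(rand8, 1)
    rand8 = rand8 + rand8.T
    return {
        "two_cliques": two_cliques,
        "barbell": barbell,
        "path7": path7,
        "clique5": clique(5),
        "random8": rand8,
    }


class TestCommunities:
    def test_disjoint_cliques_recovered(self):
        adj = sp.csr_matrix(_toy_graphs()["two_cliques"])
        lab = louvain_communities(adj, resolution=1.0, seed=0)
        assert lab.n_clusters == 2
        assert len(set(lab.labels[:4])) == 1 and len(set(lab.labels[4:])) == 1

    def test_single_clique_one_community(self):
        adj = sp.csr_matrix(_toy_graphs()["clique5"])
        lab = louvain_communities(adj, resolution=1.0, seed=0)
        assert lab.n_clusters == 1

    @pytest.mark.parametrize("name", list(_toy_graphs()))
    @pytest.mark.parametrize("resolution", [0.85, 1.0])
    def test_achieves_exhaustive_max_modularity(self, name, resolution):
        adj = _toy_graphs()[name]
        n = adj.shape[0]
        best = max(
            modularity(sp.csr_matrix(adj), part, resolution)
            for part in _all_partitions(n)
        )
        lab = louvain_communities(sp.csr_matrix(adj), resolution=resolution, seed=0)
        got = modularity(sp.csr_matrix(adj), lab.labels, resolution)
        assert got == pytest.approx(best, abs=1e-9)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_communities(sp.csr_matrix((0, 0)), 1.0, 0)

    def test_seeded_determinism(self, small_sim):
        (cm, _), _ = small_sim
        from evmap.qc import qc_overcluster

        l1 = qc_overcluster(cm, resolution=0.85, seed=9)
        l2 = qc_overcluster(cm, resolution=0.85, seed=9)
        np.testing.assert_array_equal(l1.labels, l2.labels)


class TestFinalMapARI:
    def test_planted_types_recovered(self, small_sim):
        (cm, truth), _ = small_sim
        from evmap.qc import qc_overcluster

        lab = qc_overcluster(cm, resolution=0.85, seed=0)
        ari = adjusted_rand_score(truth.nuclei["cell_type"], lab.labels)
        assert ari >= 0.9


@pytest.fixture(scope="module")
def doublet_sim():
    cfg = SimConfig(
        n_samples=1, nuclei_per_sample=800, n_genes=600, n_de_genes=10,
        cell_type_proportions=(0.5, 0.5), recomb_prob=(0.5, 0.5),
        doublet_rate=0.08, seed=55,
    )
    cm, truth = simulate_experiment(cfg)
    scores = doublet_scores(cm, seed=0)
    return truth, scores


class TestDoublets:
    def test_planted_doublets_score_high(self, doublet_sim):
        truth, scores = doublet_sim
        dbl = truth.nuclei["doublet"].to_numpy()
        assert np.median(scores[dbl]) > np.percentile(scores[~dbl], 90)

    def test_seed_reproducibility(self, small_sim):
        (cm, _), _ = small_sim
        sub = cm.subset_nuclei(np.arange(200))
        np.testing.assert_array_equal(
            doublet_scores(sub, seed=3), doublet_scores(sub, seed=3)
        )

    def test_too_few_nuclei(self, small_sim):
        (cm, _), _ = small_sim
        with pytest.raises(ValueError):
            doublet_scores(cm.subset_nuclei(np.arange(30)), seed=0)


class TestFlagDoubletClusters:
    def test_equal_medians_flag_nothing(self):
        labels = np.repeat([0, 1, 2], 10)
        assert flag_doublet_clusters(labels, np.full(30, 0.1)) == []

    def test_hand_iqr_enriched_cluster(self):
        # medians {0.02, 0.03, 0.05, 0.8}: Q3=0.2375, IQR=0.21 -> bound 0.5575
        labels = np.repeat([0, 1, 2, 3], 5)
        scores = np.repeat([0.02, 0.03, 0.05, 0.8], 5)
        assert flag_doublet_clusters(labels, scores) == [3]

    def test_label_permutation_invariance(self):
        labels = np.repeat([0, 1, 2, 3], 5)
        scores = np.repeat([0.02, 0.03, 0.05, 0.8], 5)
        perm = np.array([2, 0, 3, 1])[labels]
        assert flag_doublet_clusters(perm, scores) == [1]
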