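"""Entropy, QC metrics and the four-step nucleus filter."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from evmap.core_io import CountMatrix
from evmap.embed_cluster import ClusterLabels
from evmap.qc import (
    QCParams,
    compute_qc_metrics,
    qc_cluster_filter,
    qc_merge_similar,
    qc_nucleus_filter,
    qc_overcluster,
    run_qc,
    shannon_entropy,
)
from evmap.synthetic import SimConfig, simulate_experiment


def _cm(dense, mito_rows=(), exon=None):
    dense = np.asarray(dense)
    g, n = dense.shape
    genes = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(g)],
         "symbol": [f"g{i}" for i in range(g)],
         "is_mito": [i in mito_rows for i in range(g)],
         "is_reporter": False}
    )
    nuclei = pd.DataFrame({"barcode": [f"bc{i}" for i in range(n)], "sample_id": "s"})
    if exon is not None:
        nuclei["exon_fraction"] = exon
    return CountMatrix(counts=sp.csr_matrix(dense), genes=genes, nuclei=nuclei)


class TestShannonEntropy:
    def test_uniform_closed_form(self):
        assert shannon_entropy([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-9)

    def test_single_support_is_zero(self):
        assert shannon_entropy([5, 0, 0]) == 0.0

    def test_hand_summed_value(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        assert shannon_entropy([2, 1, 1]) == pytest.approx(1.039721, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0, 0])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=30)
           .filter(lambda v: sum(v) > 0))
    def test_bounded_by_log_support(self, counts):
        h = shannon_entropy(counts)
        k = sum(c > 0 for c in counts)
        assert -1e-12 <= h <= np.log(k) + 1e-12


class TestComputeQCMetrics:
    def test_mito_fraction_arithmetic(self):
        cm = _cm([[5], [45]], mito_rows=(0,))
        qc = compute_qc_metrics(cm)
        assert qc["mito_frac"].iloc[0] == pytest.approx(0.1)
        assert qc["total_counts"].iloc[0] == 50

    def test_n_genes_counts_nonzero(self):
        cm = _cm([[1, 0], [2, 0], [3, 1], [0, 0]])
        qc = compute_qc_metrics(cm)
        assert list(qc["n_genes"]) == [3, 1]

    def test_entropy_matches_columnwise_oracle(self, rng):
        dense = rng.poisson(2.0, size=(30, 15)) + 1  # +1 avoids zero columns
        cm = _cm(dense)
        qc = compute_qc_metrics(cm)
        for i in range(15):
            assert qc["entropy"].iloc[i] == pytest.approx(
                shannon_entropy(dense[:, i]), abs=1e-10
            )

    def test_zero_total_nucleus_named(self):
        cm = _cm([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="bc1"):
            compute_qc_metrics(cm)


def _qc_frame(mito, entropy, exon=None, n_genes=None):
    n = len(mito)
    return pd.DataFrame(
        {"barcode": [f"b{i}" for i in range(n)], "sample_id": "s",
         "n_genes": n_genes if n_genes is not None else np.full(n, 500),
         "total_counts": 1000, "mito_frac": mito,
         "exon_frac": exon if exon is not None else np.full(n, np.nan),
         "entropy": entropy}
    )


class TestClusterFilter:
    def test_hand_quartile_mito_rule(self):
        # cluster medians {0.01, 0.01, 0.02, 0.02, 0.5}: Q3=0.02, IQR=0.01 -> bound 0.035
        labels = np.repeat([0, 1, 2, 3, 4], 3)
        mito = np.repeat([0.01, 0.01, 0.02, 0.02, 0.5], 3)
        rec = qc_cluster_filter(labels, _qc_frame(mito, np.full(15, 5.0)))
        mito_hits = [r for r in rec if r["metric"] == "mito_frac"]
        assert [r["cluster"] for r in mito_hits] == [4]
        assert mito_hits[0]["bound"] == pytest.approx(0.035)

    def test_equal_medians_remove_nothing(self):
        labels = np.repeat([0, 1, 2], 4)
        rec = qc_cluster_filter(labels, _qc_frame(np.full(12, 0.01), np.full(12, 5.0)))
        assert [r for r in rec if r["cluster"] >= 0] == []

    def test_low_entropy_cluster_removed(self):
        labels = np.repeat([0, 1, 2, 3, 4], 2)
        entropy = np.repeat([5.0, 5.0, 5.1, 4.9, 0.1], 2)
        rec = qc_cluster_filter(labels, _qc_frame(np.full(10, 0.01), entropy))
        hits = [r for r in rec if r["metric"] == "entropy"]
        assert [r["cluster"] for r in hits] == [4]

    def test_label_permutation_invariance(self, rng):
        labels = np.repeat([0, 1, 2, 3], 5)
        mito = rng.uniform(0, 0.03, 20)
        mito[labels == 2] = 0.8
        qc = _qc_frame(mito, np.full(20, 5.0))
        rec1 = qc_cluster_filter(labels, qc)
        perm = np.array([3, 2, 1, 0])[labels]  # relabel clusters
        rec2 = qc_cluster_filter(perm, qc)
        assert {3 - r["cluster"] for r in rec1 if r["cluster"] >= 0} == {
            r["cluster"] for r in rec2 if r["cluster"] >= 0
        }


class TestMergeSimilar:
    def test_identical_centroids_merge(self, rng):
        dense = np.tile(rng.poisson(3.0, size=(40, 1)), (1, 20)) + rng.poisson(1, (40, 20))
        cm = _cm(dense)
        labels = ClusterLabels(labels=np.repeat([0, 1], 10), resolution=2.0)
        # same generating profile on both halves -> correlation distance ~ 0
        merged = qc_merge_similar(labels, cm, merge_height=0.1)
        assert merged.n_clusters == 1

    def test_distinct_centroids_stay_separate(self, rng):
        a = rng.poisson(5.0, size=(40, 10))
        b = rng.poisson(5.0, size=(40, 10))
        b[:20] *= 6  # different expression shape
        cm = _cm(np.hstack([a, b]))
        labels = ClusterLabels(labels=np.repeat([0, 1], 10), resolution=2.0)
        merged = qc_merge_similar(labels, cm, merge_height=0.05)
        assert merged.n_clusters == 2

    def test_single_cluster_unchanged(self, rng):
        cm = _cm(rng.poisson(2.0, (30, 8)) + 1)
        merged = qc_merge_similar(np.zeros(8, int), cm, merge_height=0.1)
        assert merged.n_clusters == 1


class TestNucleusFilter:
    def test_min_genes_hard_rule(self):
        qc = _qc_frame(np.full(25, 0.01), np.full(25, 5.0),
                       n_genes=np.r_[np.full(24, 500), 100])
        keep, reasons = qc_nucleus_filter(
            np.zeros(25, int), qc, contamination=0.0, pct=100.0)
        assert not keep[-1]
        assert reasons.set_index("barcode").loc["b24", "reason"] == "min_genes"

    def test_max_mito_hard_rule(self):
        mito = np.full(25, 0.01)
        mito[3] = 0.10
        qc = _qc_frame(mito, np.full(25, 5.0))
        keep, reasons = qc_nucleus_filter(
            np.zeros(25, int), qc, contamination=0.0, pct=100.0)
        assert not keep[3]
        assert reasons.set_index("barcode").loc["b3", "reason"] == "max_mito"

    def test_planted_10_sigma_outlier_flagged(self, rng):
        n = 100
        mito = rng.normal(0.02, 0.002, n).clip(0, 1)
        ent = rng.normal(5.0, 0.1, n)
        mito[0] = 0.02 + 10 * 0.002  # 10 sigma
        ent[0] = 5.0 + 10 * 0.1
        qc = _qc_frame(mito, ent)
        keep, reasons = qc_nucleus_filter(
            np.zeros(n, int), qc, contamination=0.05, pct=100.0,
            min_genes=0, max_mito=1.1, seed=0)
        flagged = set(reasons.loc[reasons["reason"] == "mcd_outlier", "barcode"])
        assert "b0" in flagged
        assert len(flagged) == 5  # contamination 0.05 of n=100

    def test_small_cluster_skips_mcd(self):
        qc = _qc_frame(np.full(10, 0.01), np.full(10, 5.0))
        keep, reasons = qc_nucleus_filter(
            np.zeros(10, int), qc, contamination=0.05, pct=100.0)
        assert keep.all()
        assert any(n["note"] == "mcd_skipped_small_cluster"
                   for n in reasons.attrs["notes"])


class TestOvercluster:
    def test_separated_types_give_pure_clusters(self, small_sim):
        (cm, truth), _ = small_sim
        labels = qc_overcluster(cm, resolution=2.0, seed=0)
        assert labels.n_clusters >= 2
        # every substantive cluster should be >=95% one planted type
        # (tiny residual clusters of a few nuclei are expected at resolution 2)
        ct = truth.nuclei["cell_type"].to_numpy()
        n_covered = 0
        for c in range(labels.n_clusters):
            mask = labels.labels == c
            if mask.sum() < 20:
                continue
            purity = np.bincount(ct[mask]).max() / mask.sum()
            assert purity >= 0.95
            n_covered += mask.sum()
        assert n_covered >= 0.95 * len(labels)

    def test_seed_reproducibility(self, small_sim):
        (cm, _), _ = small_sim
        l1 = qc_overcluster(cm, seed=4)
        l2 = qc_overcluster(cm, seed=4)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_too_few_nuclei_rejected(self, rng):
        cm = _cm(rng.poisson(2.0, (40, 10)) + 1)
        with pytest.raises(ValueError):
            qc_overcluster(cm)


@pytest.fixture(scope="module")
def qc_run():
    cfg = SimConfig(n_samples=2, nuclei_per_sample=800, n_genes=800,
                    n_de_genes=20, lowq_fraction=0.05, seed=33)
    cm, truth = simulate_experiment(cfg)
    cms = [cm.subset_nuclei(np.asarray(cm.nuclei["sample_id"] == s))
           for s in ("sample0", "sample1")]
    filtered, report = run_qc(cms, QCParams(), seed=0)
    return cms, truth, filtered, report


class TestRunQC:
    def test_conservation_per_sample(self, qc_run):
        cms, _, filtered, report = qc_run
        for cm in cms:
            s = cm.nuclei["sample_id"].iloc[0]
            rec = report.per_sample[s]
            n_out = (filtered.nuclei["sample_id"] == s).sum()
            assert rec["n_input"] == (
                n_out + len(rec["cluster_removed_nuclei"]) + len(rec["nucleus_removed"])
            )

    def test_planted_lowq_mostly_removed(self, qc_run):
        _, truth, filtered, _ = qc_run
        kept = set(zip(filtered.nuclei["barcode"], filtered.nuclei["sample_id"]))
        lowq = truth.nuclei[truth.nuclei["lowq"]]
        removed = [1 - ((b, s) in kept) for b, s in zip(lowq["barcode"], lowq["sample_id"])]
        assert np.mean(removed) >= 0.90

    def test_no_removed_nucleus_survives(self, qc_run):
        _, _, filtered, report = qc_run
        kept = set(zip(filtered.nuclei["barcode"], filtered.nuclei["sample_id"]))
        for s, rec in report.per_sample.items():
            for b in rec["nucleus_removed"]:
                assert (b, s) not in kept
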