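"""Per-nucleus QC metrics and the four-step cluster-aware nucleus filter.

The procedure runs independently per sample to respect distributional
differences between libraries:

1. overcluster at high resolution (default 2.0);
2. remove whole clusters whose median mitochondrial fraction or median
   exonic fraction exceeds Q3 + 1.5 IQR of the cluster medians, or whose
   median entropy falls below Q1 - 1.5 IQR;
3. merge similar clusters by average-linkage hierarchical clustering of
   centroids under correlation distance;
4. within each merged cluster, flag robust-Mahalanobis outliers over
   (mito fraction, exonic fraction, entropy) at a fixed contamination, and
   remove nuclei whose ln(n_genes) * entropy exceeds the cluster's 90th
   percentile; finally apply the hard filters (< 150 genes detected or
   mitochondrial fraction > 0.05).

Entropy is the plug-in Shannon estimator in nats.  Quartiles use linear
interpolation (numpy default), stated here because IQR fences are sensitive
to the quartile convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from sklearn.covariance import EllipticEnvelope

from .core_io import CountMatrix, concat_nuclei
from .embed_cluster import (
    ClusterLabels,
    knn_graph,
    louvain_communities,
    normalize_log1p,
    pca_latent,
    select_hvg,
)


def shannon_entropy(counts) -> float:
    """Plug-in Shannon entropy (nats) of a nonnegative count vector."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("entropy undefined for an all-zero vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def compute_qc_metrics(cm: CountMatrix) -> pd.DataFrame:
    """One row per nucleus: n_genes, total_counts, mito_frac, exon_frac, entropy.

    ``exon_frac`` is copied from the nucleus metadata when present and NaN
    otherwise.  A nucleus with zero total counts raises, naming its barcode.
    """
    X = cm.counts.tocsc()
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = cm.nuclei["barcode"].iloc[int(np.argmin(totals))]
        raise ValueError(f"nucleus {bad!r} has zero total counts")
    n_genes = X.getnnz(axis=0)
    mito = np.asarray(X[cm.genes["is_mito"].to_numpy(), :].sum(axis=0)).ravel()
    entropy = np.empty(cm.n_nuclei)
    for i in range(cm.n_nuclei):
        col = X.data[X.indptr[i] : X.indptr[i + 1]]
        p = col / totals[i]
        entropy[i] = float(-(p * np.log(p)).sum())
    out = pd.DataFrame(
        {
            "barcode": cm.nuclei["barcode"].to_numpy(),
            "sample_id": cm.nuclei["sample_id"].to_numpy(),
            "n_genes": n_genes.astype(int),
            "total_counts": totals.astype(int),
            "mito_frac": mito / totals,
            "exon_frac": cm.nuclei["exon_fraction"].to_numpy()
            if "exon_fraction" in cm.nuclei.columns
            else np.nan,
            "entropy": entropy,
        }
    )
    return out


def qc_overcluster(
    cm: CountMatrix,
    resolution: float = 2.0,
    seed: int = 0,
    n_hvg: int = 2000,
    d: int = 50,
    k: int = 15,
) -> ClusterLabels:
    """High-resolution clustering for QC (normalize -> HVG -> PCA -> kNN -> communities)."""
    if cm.n_nuclei < 2 * k:
        raise ValueError(f"need at least {2 * k} nuclei, got {cm.n_nuclei}")
    norm = normalize_log1p(cm)
    hvg = select_hvg(cm, n_hvg=min(n_hvg, cm.n_genes))
    mat = np.asarray(norm[hvg, :].T.todense())
    emb = pca_latent(mat, d=min(d, min(mat.shape)))
    graph = knn_graph(emb, k=k, metric="cosine")
    return louvain_communities(graph, resolution=resolution, seed=seed)


def _iqr_fences(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def qc_cluster_filter(
    labels: ClusterLabels | np.ndarray, qc: pd.DataFrame
) -> list[dict]:
    """Whole-cluster removal by IQR fences on cluster-median QC metrics.

    High fences for mito_frac and exon_frac; low fence for entropy.  Returns
    a list of {cluster, metric, median, bound} records.  If exon_frac is all
    NaN that rule is skipped (recorded with metric "exon_frac_skipped").
    """
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    removed: list[dict] = []

    def medians_of(col):
        return np.array([np.median(qc[col].to_numpy()[lab == c]) for c in uniq])

    for col in ("mito_frac", "exon_frac"):
        vals = qc[col].to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            removed.append({"cluster": -1, "metric": "exon_frac_skipped", "median": np.nan, "bound": np.nan})
            continue
        med = medians_of(col)
        _, hi = _iqr_fences(med)
        for c, m in zip(uniq, med):
            if m > hi:
                removed.append({"cluster": int(c), "metric": col, "median": float(m), "bound": float(hi)})
    med = medians_of("entropy")
    lo, _ = _iqr_fences(med)
    for c, m in zip(uniq, med):
        if m < lo:
            removed.append({"cluster": int(c), "metric": "entropy", "median": float(m), "bound": float(lo)})
    return removed


def qc_merge_similar(
    labels: ClusterLabels | np.ndarray,
    cm: CountMatrix,
    merge_height: float = 0.1,
) -> ClusterLabels:
    """Merge clusters by average-linkage on centroid correlation distance.

    Centroids are mean log-normalized expression per cluster; clusters whose
    dendrogram merge height is below ``merge_height`` collapse to one label.
    """
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    res = labels.resolution if isinstance(labels, ClusterLabels) else float("nan")
    uniq = np.unique(lab)
    if uniq.size == 1:
        return ClusterLabels(labels=np.zeros_like(lab), resolution=res)
    norm = normalize_log1p(cm)
    centroids = np.vstack(
        [np.asarray(norm[:, lab == c].mean(axis=1)).ravel() for c in uniq]
    )
    z = sch.linkage(centroids, method="average", metric="correlation")
    merged = sch.fcluster(z, t=merge_height, criterion="distance")
    mapping = {c: m for c, m in zip(uniq, merged)}
    new = np.array([mapping[v] for v in lab])
    # contiguous relabel by first occurrence
    out = np.empty_like(new)
    seen: dict[int, int] = {}
    for i, v in enumerate(new):
        if v not in seen:
            seen[v] = len(seen)
        out[i] = seen[v]
    return ClusterLabels(labels=out, resolution=res)


#: minimum cluster size for the robust-covariance outlier step
MIN_MCD_CLUSTER = 20


def qc_nucleus_filter(
    labels: ClusterLabels | np.ndarray,
    qc: pd.DataFrame,
    contamination: float = 0.05,
    pct: float = 90.0,
    min_genes: int = 150,
    max_mito: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Within-cluster outlier removal plus hard filters.

    Returns (keep mask, reasons table).  Reasons, in precedence order:
    ``mcd_outlier``, ``complexity_pct``, ``min_genes``, ``max_mito``.
    Clusters smaller than MIN_MCD_CLUSTER skip the robust-covariance step
    (recorded with reason ``mcd_skipped_small_cluster`` on no nucleus).
    """
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    n = len(qc)
    remove_reason = np.array([""] * n, dtype=object)
    notes: list[dict] = []

    have_exon = not qc["exon_frac"].isna().all()
    cols = ["mito_frac", "exon_frac", "entropy"] if have_exon else ["mito_frac", "entropy"]

    for c in np.unique(lab):
        idx = np.flatnonzero(lab == c)
        feats = qc.iloc[idx][cols].to_numpy(dtype=float)
        if idx.size < MIN_MCD_CLUSTER:
            notes.append({"cluster": int(c), "note": "mcd_skipped_small_cluster"})
        elif contamination > 0:
            try:
                env = EllipticEnvelope(
                    contamination=contamination, random_state=seed
                ).fit(feats)
                flagged = env.predict(feats) == -1
                for i in idx[flagged]:
                    remove_reason[i] = "mcd_outlier"
            except ValueError:
                # singular covariance (e.g. a constant metric in the cluster)
                notes.append({"cluster": int(c), "note": "mcd_singular_skipped"})
        # complexity rule: ln(n_genes) * entropy above the cluster percentile
        comp = np.log(qc["n_genes"].to_numpy(dtype=float)[idx]) * qc["entropy"].to_numpy()[idx]
        bound = np.percentile(comp, pct)
        for i, v in zip(idx, comp):
            if v > bound and remove_reason[i] == "":
                remove_reason[i] = "complexity_pct"

    low_genes = qc["n_genes"].to_numpy() < min_genes
    high_mito = qc["mito_frac"].to_numpy() > max_mito
    for i in range(n):
        if remove_reason[i] == "":
            if low_genes[i]:
                remove_reason[i] = "min_genes"
            elif high_mito[i]:
                remove_reason[i] = "max_mito"

    keep = remove_reason == ""
    reasons = pd.DataFrame(
        {
            "barcode": qc["barcode"].to_numpy()[~keep],
            "reason": remove_reason[~keep],
        }
    )
    reasons.attrs["notes"] = notes
    return keep, reasons


@dataclass
class QCParams:
    resolution: float = 2.0
    n_hvg: int = 2000
    latent_dim: int = 50
    knn: int = 15
    merge_height: float = 0.1
    contamination: float = 0.05
    entropy_pct: float = 90.0
    min_genes: int = 150
    max_mito: float = 0.05


@dataclass
class QCReport:
    """Per-sample accounting of every removal with its reason."""

    per_sample: dict[str, dict] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for sample, rec in self.per_sample.items():
            rows.append(
                {
                    "sample_id": sample,
                    "n_input": rec["n_input"],
                    "n_removed_cluster": len(rec["cluster_removed_nuclei"]),
                    "n_removed_nucleus": len(rec["nucleus_removed"]),
                    "n_survivors": rec["n_survivors"],
                }
            )
        return pd.DataFrame(rows)


def run_qc(
    cms: list[CountMatrix],
    params: QCParams | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, QCReport]:
    """Apply the four-step QC independently per sample, then concatenate.

    Each element of ``cms`` is one sample's CountMatrix.  The report records
    every removed nucleus with its reason; input = survivors + removed.
    """
    params = params or QCParams()
    report = QCReport()
    survivors: list[CountMatrix] = []
    for cm in cms:
        sample = str(cm.nuclei["sample_id"].iloc[0])
        qc = compute_qc_metrics(cm)
        labels = qc_overcluster(
            cm,
            resolution=params.resolution,
            seed=seed,
            n_hvg=params.n_hvg,
            d=params.latent_dim,
            k=params.knn,
        )
        cluster_removals = qc_cluster_filter(labels, qc)
        bad_clusters = {r["cluster"] for r in cluster_removals if r["cluster"] >= 0}
        in_bad = np.isin(labels.labels, list(bad_clusters))
        cluster_removed = qc["barcode"].to_numpy()[in_bad]

        cm2 = cm.subset_nuclei(~in_bad)
        qc2 = qc.loc[~in_bad].reset_index(drop=True)
        lab2 = ClusterLabels(labels=labels.labels[~in_bad], resolution=labels.resolution)
        merged = qc_merge_similar(lab2, cm2, merge_height=params.merge_height)
        keep, reasons = qc_nucleus_filter(
            merged,
            qc2,
            contamination=params.contamination,
            pct=params.entropy_pct,
            min_genes=params.min_genes,
            max_mito=params.max_mito,
            seed=seed,
        )
        survivors.append(cm2.subset_nuclei(keep))
        report.per_sample[sample] = {
            "n_input": cm.n_nuclei,
            "cluster_filter_records": cluster_removals,
            "cluster_removed_nuclei": list(cluster_removed),
            "nucleus_removed": dict(zip(reasons["barcode"], reasons["reason"])),
            "n_survivors": int(keep.sum()),
        }
    return concat_nuclei(survivors), report
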