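"""Cluster marker genes by AUROC and log fold-change, and cell-type labels.

A gene is a marker of a cluster when, treating its normalized expression as
a classifier score for membership of that cluster, the area under the ROC
curve exceeds 0.7 and the natural-log fold-change of mean normalized
expression (cluster vs. the rest) exceeds 1.  Both thresholds are strict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

EPS = 1e-9  # pseudocount guarding empty-expression divisions


def gene_auc(values_in: np.ndarray, values_rest: np.ndarray) -> float:
    """Rank-based AUROC with half credit for ties (Mann-Whitney U / n1 n2)."""
    a = np.asarray(values_in, float)
    b = np.asarray(values_rest, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([a, b]))  # average ranks give ties half credit
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def cluster_log_fc(
    norm: sp.spmatrix | np.ndarray, labels: np.ndarray, cluster: int
) -> np.ndarray:
    """Per-gene ln((mean_in + eps) / (mean_rest + eps)); norm is genes x nuclei."""
    labels = np.asarray(labels)
    mask = labels == cluster
    if not mask.any():
        raise ValueError(f"cluster {cluster} is empty")
    if mask.all():
        raise ValueError("cluster equals all nuclei; no rest group")
    if sp.issparse(norm):
        mean_in = np.asarray(norm[:, mask].mean(axis=1)).ravel()
        mean_rest = np.asarray(norm[:, ~mask].mean(axis=1)).ravel()
    else:
        norm = np.asarray(norm, float)
        mean_in = norm[:, mask].mean(axis=1)
        mean_rest = norm[:, ~mask].mean(axis=1)
    return np.log((mean_in + EPS) / (mean_rest + EPS))


def find_markers(
    norm: sp.spmatrix | np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str] | None = None,
    auc_min: float = 0.7,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """All (cluster, gene) pairs passing both strict thresholds.

    ``norm`` is log1p-normalized expression (genes x nuclei).  The AUC is
    computed on it directly (the rank statistic is invariant to the log);
    the fold-change compares means on the linear normalized scale
    (expm1 back-transform), the usual single-cell convention, so a gene
    expressed at fold f in a cluster has log_fc near ln f.  Returns columns
    cluster, gene, auc, log_fc, pct_in, pct_out sorted by (cluster, auc
    descending).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    dense = np.asarray(norm.todense()) if sp.issparse(norm) else np.asarray(norm, float)
    n_genes = dense.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]

    dense_lin = np.expm1(dense)
    records = []
    for c in uniq:
        mask = labels == c
        lfc = cluster_log_fc(dense_lin, labels, c)
        cand = np.flatnonzero(lfc > lfc_min)  # AUC is the costly part; gate on lfc
        for g in cand:
            auc = gene_auc(dense[g, mask], dense[g, ~mask])
            if auc > auc_min:
                records.append(
                    {
                        "cluster": int(c),
                        "gene": gene_ids[g],
                        "auc": auc,
                        "log_fc": float(lfc[g]),
                        "pct_in": float((dense[g, mask] > 0).mean()),
                        "pct_out": float((dense[g, ~mask] > 0).mean()),
                    }
                )
    df = pd.DataFrame(
        records, columns=["cluster", "gene", "auc", "log_fc", "pct_in", "pct_out"]
    )
    if len(df):
        df = df.sort_values(["cluster", "auc"], ascending=[True, False]).reset_index(
            drop=True
        )
    return df


def assign_cell_types(
    marker_table: pd.DataFrame, reference: dict[str, list[str]]
) -> dict[int, str]:
    """Assign each cluster the reference type with maximal marker overlap.

    The overlap score is the count of a type's dictionary markers among the
    cluster's marker genes; ties (including all-zero) give "unassigned".
    """
    if not reference:
        raise ValueError("reference marker dictionary is empty")
    out: dict[int, str] = {}
    for c, sub in marker_table.groupby("cluster"):
        genes = set(sub["gene"])
        scores = {t: len(genes & set(gs)) for t, gs in reference.items()}
        best = max(scores.values())
        winners = [t for t, s in scores.items() if s == best]
        out[int(c)] = winners[0] if best > 0 and len(winners) == 1 else "unassigned"
    return out
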