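"""Over-representation analysis and preranked gene-set enrichment.

ORA is the hypergeometric upper tail P(X >= k) of the overlap between a
query gene list and each gene set, with the universe being the full list of
detected genes; up- and down-regulated queries are run separately.  The
preranked statistic is the weighted Kolmogorov-Smirnov running-sum
enrichment score (weight p = 1 on |ranking statistic|) with a gene-label
permutation null.  Multiplicity control is Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection


def bh_adjust(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_hypergeometric(
    query: list[str],
    universe: list[str],
    gene_sets: GeneSetCollection | dict[str, list[str]],
    direction_tag: str = "",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within each set.

    Sets are intersected with the universe first; p = P(X >= k) under
    Hypergeometric(N, K, n).  BH adjustment across sets; significance at
    p_adj < 0.05 by convention of the surrounding pipeline.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q = set(query) & uni
    if set(query) - uni:
        raise ValueError("query genes outside the universe")
    sets = gene_sets.as_dict() if isinstance(gene_sets, GeneSetCollection) else gene_sets
    n_uni = len(uni)
    n_q = len(q)
    rows = []
    for name, members in sets.items():
        k_set = set(members) & uni
        overlap = len(q & k_set)
        # P(X >= k) = hypergeom.sf(k - 1)
        p = float(scipy.stats.hypergeom.sf(overlap - 1, n_uni, len(k_set), n_q))
        rows.append(
            {
                "set": name,
                "mode": "ORA",
                "direction": direction_tag,
                "overlap": overlap,
                "set_size": len(k_set),
                "universe": n_uni,
                "query": n_q,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def _enrichment_score(ranked_stats: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Signed max deviation of the weighted KS running sum."""
    if weight == 0:
        hit_w = in_set.astype(float)
    else:
        hit_w = np.abs(ranked_stats) ** weight * in_set
    total_hit = hit_w.sum()
    n = len(in_set)
    n_miss = n - int(in_set.sum())
    if total_hit == 0 or n_miss == 0:
        raise ValueError("set must hit and miss at least one ranked gene")
    running = np.cumsum(hit_w / total_hit - (~in_set).astype(float) / n_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranked_genes: list[str],
    ranking_stats: np.ndarray,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> dict:
    """Weighted-KS enrichment of ``gene_set`` in a ranked gene list.

    ``ranked_genes`` must be ordered by ``ranking_stats`` descending (the
    caller ranks by log2 fold-change).  The null permutes gene labels;
    perm_p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1); NES divides ES by
    the mean |ES_perm| of the same sign.
    """
    stats = np.asarray(ranking_stats, float)
    if len(ranked_genes) != len(stats):
        raise ValueError("ranked_genes and ranking_stats must align")
    members = set(gene_set)
    in_set = np.array([g in members for g in ranked_genes])
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set disjoint from the ranked list")
    if k == len(ranked_genes):
        raise ValueError("gene set equals the ranked list")
    es = _enrichment_score(stats, in_set, weight)

    rng = np.random.default_rng(seed)
    n = len(ranked_genes)
    perm_es = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        perm_es[b] = _enrichment_score(stats, mask, weight)
    perm_p = float((1 + np.sum(np.abs(perm_es) >= abs(es))) / (n_perm + 1))
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    denom = np.mean(np.abs(same_sign)) if same_sign.size else np.nan
    nes = float(es / denom) if denom and not np.isnan(denom) else np.nan
    return {
        "mode": "GSEA",
        "es": es,
        "nes": nes,
        "perm_p": perm_p,
        "n_perm": n_perm,
        "set_hits": k,
    }
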