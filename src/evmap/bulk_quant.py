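"""Bulk-count utilities: RPM normalization, two-group fold filtering, and
miRNA composition summaries.

These support the two small bulk arms of the study design: the reporter-cell
two-group comparison (features expressed at >= 25 reads per million with a
twofold change between groups) and the pooled plasma-EV miRNA composition
(per-miRNA percentage of total signal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EPS = 1e-9


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million per sample column: rpm = 1e6 * c / colsum."""
    sums = counts.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"zero library size for sample(s) {bad}")
    return counts * (1e6 / sums)


def fold_filter(
    rpm_mean_a: pd.Series | np.ndarray,
    rpm_mean_b: pd.Series | np.ndarray,
    min_rpm: float = 25.0,
    min_fold: float = 2.0,
) -> np.ndarray:
    """Features expressed (max group mean >= min_rpm) with a fold change
    >= min_fold in either direction; boundaries inclusive.

    Returns a boolean keep mask aligned with the input.
    """
    a = np.asarray(rpm_mean_a, float)
    b = np.asarray(rpm_mean_b, float)
    expressed = np.maximum(a, b) >= min_rpm
    # cross-multiplied comparison keeps the boundary inclusive without an
    # epsilon perturbing exact ratios
    folded = (a + EPS >= min_fold * b) | (b + EPS >= min_fold * a)
    return expressed & folded


def mirna_fraction(
    counts: pd.DataFrame, pool_samples: list[str] | None = None, top_k: int = 20
) -> pd.DataFrame:
    """Per-miRNA percentage of total pooled signal, descending.

    Counts are summed across ``pool_samples`` (default: all columns) before
    normalising, mirroring pooling of samples that passed QC.  Returns a
    table (feature, pooled_count, pct) sorted by pct descending, with the
    full table in ``.attrs["all"]`` and the top ``top_k`` as the frame.
    """
    cols = list(counts.columns) if pool_samples is None else list(pool_samples)
    if not cols:
        raise ValueError("empty sample pool")
    pooled = counts[cols].sum(axis=1)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("pooled counts are not positive")
    pct = 100.0 * pooled / total
    full = (
        pd.DataFrame({"feature": counts.index, "pooled_count": pooled.to_numpy(), "pct": pct.to_numpy()})
        .sort_values("pct", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    out = full.head(top_k).copy()
    out.attrs["all"] = full
    return out
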