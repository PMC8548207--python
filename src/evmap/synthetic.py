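"""Synthetic multi-sample reporter snRNA-seq data with planted ground truth.

The generator emulates the structure of a dual-fluorescence Cre/lox reporter
experiment: several mice (samples), each contributing a few thousand nuclei
drawn from a fixed set of cell types; cell-type marker genes with a known
fold; a recombination indicator per nucleus whose probability depends on the
cell type (on the logit scale) plus a per-sample shift; mutually exclusive
eGFP / tdTomato reporter transcripts; negative-binomial overdispersion;
differential-expression effects on recombined nuclei with per-sample random
intercepts; and planted low-quality nuclei (high mitochondrial fraction,
concentrated low-entropy expression, aberrant exonic fraction) and doublets.

Everything is reproducible from the seed carried in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix

N_MITO_GENES = 13  # matches the size of the mammalian mitochondrial gene set


@dataclass
class SimConfig:
    """Parameters of a simulated reporter experiment.

    Defaults are desk-scale study conditions: 3 samples of 2,000 nuclei
    (the real experiment used 6 mice at ~5,000-nucleus loading), 5 cell
    types with distinct recombination probabilities, markers at fold e^2,
    and a DE effect of 0.5 on the log scale.
    """

    n_samples: int = 3
    nuclei_per_sample: int = 2000
    n_genes: int = 2000
    cell_type_proportions: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.10)
    nb_dispersion: float = 2.0
    markers_per_type: int = 10
    marker_fold: float = float(np.exp(2.0))
    recomb_prob: tuple[float, ...] = (0.50, 0.35, 0.60, 0.20, 0.45)
    sample_logit_sd: float = 0.15
    n_de_genes: int = 50
    de_beta: float = 0.5
    de_sigma_re: float = 0.10
    lowq_fraction: float = 0.0
    doublet_rate: float = 0.0
    mean_depth: float = 2000.0
    reporter_mean: float = 3.0
    double_positive_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.cell_type_proportions, float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cell_type_proportions must sum to 1")
        if len(self.recomb_prob) != len(props):
            raise ValueError("recomb_prob must have one entry per cell type")
        if not all(0.0 <= p <= 1.0 for p in self.recomb_prob):
            raise ValueError("recomb_prob entries must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if not (0.0 <= self.lowq_fraction < 1.0):
            raise ValueError("lowq_fraction must lie in [0, 1)")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must lie in [0, 1)")
        if self.sample_logit_sd < 0:
            raise ValueError("sample_logit_sd must be >= 0")
        if self.reporter_mean < 1:
            raise ValueError("reporter_mean must be >= 1")
        n_types = len(props)
        if self.markers_per_type * n_types + self.n_de_genes + N_MITO_GENES > self.n_genes:
            raise ValueError("markers + DE genes + mito genes exceed n_genes")

    @property
    def n_types(self) -> int:
        return len(self.cell_type_proportions)


@dataclass
class SimTruth:
    """Planted truth accompanying a simulated experiment."""

    nuclei: pd.DataFrame  # barcode, sample_id, cell_type, recombined, doublet, lowq
    samples: pd.DataFrame  # sample_id, logit_shift, de_intercepts (per-sample RE)
    genes: pd.DataFrame  # gene_id, marker_of, marker_fold, de_beta


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_experiment(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw one multi-sample experiment; identical output for identical cfg."""
    rng = np.random.default_rng(cfg.seed)
    n_types = cfg.n_types
    n_genes = cfg.n_genes

    # gene annotation: mito genes first, then body genes, then the two reporters
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    symbols = list(gene_ids)
    for i in range(N_MITO_GENES):
        symbols[i] = f"mt-g{i + 1}"

    # log-normal baseline expression shared across types
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[:N_MITO_GENES] = base[:N_MITO_GENES].mean()  # steady modest mito load

    # assign marker genes per type (disjoint blocks after the mito block)
    marker_of = np.full(n_genes, -1)
    ptr = N_MITO_GENES
    for t in range(n_types):
        marker_of[ptr : ptr + cfg.markers_per_type] = t
        ptr += cfg.markers_per_type
    de_beta = np.zeros(n_genes)
    de_idx = np.arange(ptr, ptr + cfg.n_de_genes)
    de_beta[de_idx] = cfg.de_beta

    # per-type mean profiles
    profiles = np.tile(base, (n_types, 1))
    for t in range(n_types):
        profiles[t, marker_of == t] *= cfg.marker_fold

    # per-sample shifts: recombination logit and per-gene-free DE random intercept
    logit_shift = rng.normal(0.0, cfg.sample_logit_sd, size=cfg.n_samples)
    de_re = rng.normal(0.0, cfg.de_sigma_re, size=cfg.n_samples)

    blocks: list[sp.csr_matrix] = []
    nuc_rows = []
    logit_p = np.log(np.asarray(cfg.recomb_prob, float) + 1e-12) - np.log1p(
        -np.asarray(cfg.recomb_prob, float) + 1e-12
    )

    for s in range(cfg.n_samples):
        n = cfg.nuclei_per_sample
        types = rng.choice(n_types, size=n, p=np.asarray(cfg.cell_type_proportions))
        p_rec = _sigmoid(logit_p[types] + logit_shift[s])
        # honour exact 0/1 probabilities despite the logit transform
        hard = np.asarray(cfg.recomb_prob, float)[types]
        p_rec = np.where(hard == 0.0, 0.0, np.where(hard == 1.0, 1.0, p_rec))
        recombined = rng.random(n) < p_rec

        lowq = rng.random(n) < cfg.lowq_fraction
        depth = cfg.mean_depth * rng.lognormal(0.0, 0.3, size=n)

        # per-nucleus expected profile
        mean_mat = profiles[types].astype(float)  # n x n_genes
        # DE effect: beta on recombined nuclei + per-sample random intercept
        # (intercept applies to all nuclei of the sample, matching the GLMM)
        mult = np.exp(de_re[s] + np.where(recombined, cfg.de_beta, 0.0))
        mean_mat[:, de_idx] *= mult[:, None]

        # low-quality nuclei: inflated mito share + concentrated expression
        if lowq.any():
            idx = np.flatnonzero(lowq)
            for i in idx:
                prof = mean_mat[i].copy()
                conc = rng.choice(np.arange(N_MITO_GENES, n_genes), size=20, replace=False)
                newp = np.zeros_like(prof)
                newp[conc] = prof[conc] + prof.sum() / 20.0
                # mito-heavy: ~40% of the library on the mito block
                newp[:N_MITO_GENES] = 0.67 * prof.sum() / N_MITO_GENES
                mean_mat[i] = newp

        mean_mat /= mean_mat.sum(axis=1, keepdims=True)
        mu = mean_mat * depth[:, None]
        lam = rng.gamma(shape=cfg.nb_dispersion, scale=mu / cfg.nb_dispersion)
        counts = rng.poisson(lam).astype(np.int64)  # nuclei x genes

        # doublets: replace a fraction with sums of two random singlet rows
        doublet = np.zeros(n, dtype=bool)
        if cfg.doublet_rate > 0:
            n_dbl = int(round(cfg.doublet_rate * n))
            if n_dbl:
                tgt = rng.choice(n, size=n_dbl, replace=False)
                partners = rng.integers(0, n, size=(n_dbl, 2))
                counts[tgt] = counts[partners[:, 0]] + counts[partners[:, 1]]
                doublet[tgt] = True

        # reporter counts (mutually exclusive unless double-positive leak)
        egfp = np.zeros(n, dtype=np.int64)
        tom = np.zeros(n, dtype=np.int64)
        egfp[recombined] = rng.poisson(cfg.reporter_mean, size=recombined.sum())
        tom[~recombined] = rng.poisson(cfg.reporter_mean, size=(~recombined).sum())
        if cfg.double_positive_rate > 0:
            leak_idx = np.flatnonzero(rng.random(n) < cfg.double_positive_rate)
            extra = rng.poisson(cfg.reporter_mean, size=leak_idx.size)
            rec_leak = recombined[leak_idx]
            tom[leak_idx[rec_leak]] += extra[rec_leak]
            egfp[leak_idx[~rec_leak]] += extra[~rec_leak]

        # exonic fraction: nuclei are intron-rich, so the clean Beta sits low
        exon = rng.beta(4.0, 8.0, size=n)
        exon[lowq] = rng.beta(16.0, 4.0, size=lowq.sum())

        block = sp.hstack(
            [sp.csr_matrix(counts), sp.csr_matrix(np.column_stack([egfp, tom]))],
            format="csr",
        )
        blocks.append(block.T.tocsr())  # genes x nuclei
        nuc_rows.append(
            pd.DataFrame(
                {
                    "barcode": [f"S{s}_BC{i:05d}" for i in range(n)],
                    "sample_id": f"sample{s}",
                    "exon_fraction": exon,
                    "cell_type": types,
                    "recombined": recombined,
                    "doublet": doublet,
                    "lowq": lowq,
                }
            )
        )

    all_nuclei = pd.concat(nuc_rows, ignore_index=True)
    counts_full = sp.hstack(blocks, format="csr")

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids + ["eGFP", "tdTomato"],
            "symbol": symbols + ["eGFP", "tdTomato"],
            "is_mito": [s.lower().startswith("mt-") for s in symbols] + [False, False],
            "is_reporter": [False] * n_genes + [True, True],
        }
    )
    cm = CountMatrix(
        counts=counts_full,
        genes=genes,
        nuclei=all_nuclei[["barcode", "sample_id", "exon_fraction"]].copy(),
    )
    truth = SimTruth(
        nuclei=all_nuclei[
            ["barcode", "sample_id", "cell_type", "recombined", "doublet", "lowq"]
        ].copy(),
        samples=pd.DataFrame(
            {
                "sample_id": [f"sample{s}" for s in range(cfg.n_samples)],
                "logit_shift": logit_shift,
                "de_intercept": de_re,
            }
        ),
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids + ["eGFP", "tdTomato"],
                "marker_of": list(marker_of) + [-1, -1],
                "marker_fold": [
                    cfg.marker_fold if m >= 0 else 1.0 for m in marker_of
                ]
                + [1.0, 1.0],
                "de_beta": list(de_beta) + [0.0, 0.0],
            }
        ),
    )
    return cm, truth


def simulate_bulk_table(
    n_features: int,
    group_means: dict[str, np.ndarray],
    dispersion: float,
    libsizes: dict[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a features x samples NB count table.

    ``group_means`` maps group name to a length-``n_features`` vector of
    expected reads-per-million intensities; ``libsizes`` maps sample name to
    its library size, with the group taken as the part of the sample name
    before the final underscore (e.g. ``"ctrl_1"`` is in group ``"ctrl"``).
    ``dispersion >= 1e8`` is treated as the Poisson limit.
    """
    rng = np.random.default_rng(seed)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    cols = {}
    for sample, lib in libsizes.items():
        if lib <= 0:
            raise ValueError(f"library size for {sample!r} must be positive")
        group = sample.rsplit("_", 1)[0]
        if group not in group_means:
            raise ValueError(f"no group means for sample {sample!r}")
        means = np.asarray(group_means[group], dtype=float)
        if len(means) != n_features:
            raise ValueError("group mean vector length != n_features")
        if np.any(means < 0):
            raise ValueError("feature means must be nonnegative")
        mu = means * lib / 1e6
        if dispersion >= 1e8:
            cols[sample] = rng.poisson(mu)
        else:
            lam = np.where(mu > 0, rng.gamma(dispersion, np.maximum(mu, 1e-300) / dispersion), 0.0)
            cols[sample] = rng.poisson(lam)
    df = pd.DataFrame(cols, index=[f"feat{i:04d}" for i in range(n_features)])
    df.index.name = "feature"
    return df
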