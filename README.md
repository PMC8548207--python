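# evmap

Mapping the target cells of red-blood-cell–derived extracellular vesicles
(RBC-EVs) from Cre/lox reporter single-nucleus RNA-seq.

## The problem

In the mT/mG dual-fluorescence reporter system every cell expresses
membrane tdTomato until Cre recombinase excises the cassette, switching the
cell to membrane eGFP. When Cre protein is delivered by extracellular
vesicles — here, vesicles shed by red blood cells after complement
activation — recombined (eGFP⁺) cells mark the vesicles' in-vivo targets.
Sequencing nuclei from reporter-mouse hearts then turns EV tropism into a
transcriptomic readout: which cell types recombine, at what rate, and how
gene expression differs between targeted and untargeted cells.

`evmap` implements that analysis as a tested, reusable library for nuclei ×
gene count matrices (10x-style MTX triplets):

- **Nucleus QC** — per-nucleus metrics (genes detected, mitochondrial
  fraction, exonic read fraction, plug-in Shannon entropy) and a four-step
  cluster-aware filter run independently per sample: overclustering at
  resolution 2.0; whole-cluster removal by IQR fences on cluster-median
  metrics; centroid merging; within-cluster robust-Mahalanobis outlier and
  complexity-percentile removal; hard filters (< 150 genes, mitochondrial
  fraction > 0.05).
- **Embedding and clustering** — counts-per-10k log1p normalization, 2,000
  highly variable genes, 50-component PCA, exact cosine kNN graph (k = 15),
  modularity-based community detection with a resolution parameter
  (0.85 for the final map), simulate-and-score doublet detection.
- **Markers** — per-cluster AUROC (ties get half credit) and linear-scale
  ln fold-change; markers pass AUC > 0.7 and lnFC > 1.
- **Reporter analysis** — eGFP/tdTomato calls per nucleus; among nuclei
  exclusively expressing one reporter, the per-cell-type recombination
  proportion; an effect-coded (sum-to-zero) logistic regression testing each
  type's log-odds deviation from the grand mean with a dummy-coded sample
  effect and Bonferroni correction α/K.
- **Differential expression** — per gene, a negative-binomial (fallback
  Poisson) generalized linear mixed model of counts on recombination status
  with a per-sample random intercept and log library-size offset, fitted by
  Laplace-approximated maximum likelihood:

  y<sub>i</sub> ~ NB(μ<sub>i</sub>, θ),
  log μ<sub>i</sub> = β₀ + β₁·recomb<sub>i</sub> + u<sub>s(i)</sub> + log N<sub>i</sub>,
  u<sub>s</sub> ~ N(0, σ²)

  with Wald tests on β₁ and a Bonferroni threshold α/m over the m genes
  expressed in ≥ 1% of either reporter group.
- **Enrichment** — hypergeometric over-representation against a
  detected-gene universe and preranked weighted-KS GSEA with a permutation
  null; Benjamini–Hochberg adjustment.
- **Bulk utilities** — RPM normalization, the ≥ 25 RPM / twofold two-group
  filter, and pooled miRNA composition percentages.
- **Synthetic data** — a generator planting cell types, marker folds,
  per-type recombination probabilities with per-sample shifts, DE effects
  with sample random intercepts, NB overdispersion, low-quality nuclei and
  doublets, so every stage is testable against known truth.

## Worked example

Each script in `examples/` exercises one capability. For instance:

```bash
$ python examples/02_cluster_and_markers.py
clusters found: 5  adjusted Rand index vs truth: 0.998
 cluster   gene      auc   log_fc   pct_in  pct_out
       0 G00022 0.955421 1.973224 0.997135 0.928320
       0 G00015 0.943133 1.996249 1.000000 0.828437
...
```

Five planted cell types are recovered almost perfectly (ARI 0.998), and the
top marker genes of each cluster show AUC ≈ 0.95 and ln fold-change ≈ 2 —
the planted fold. Similarly:

```bash
$ python examples/04_differential_expression.py
...
mean estimate on planted-effect genes: 0.536 (truth 0.5); on null genes: -0.015 (truth 0)
Bonferroni threshold for 50 tests: 1.00e-03
```

The mixed model recovers the planted log fold-change of 0.5 on effect genes
and stays near zero on null genes.

A thin CLI mirrors the library for shell pipelines:

```bash
evmap --seed 1 --out-dir sim simulate --n-samples 3
evmap --out-dir out qc --in-dir sim
evmap --seed 1 --out-dir out cluster --in-dir out/filtered_dir
```

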