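"""Embed, cluster and call marker genes on a simulated 5-type heart sample.

Runs the normalize -> HVG -> PCA -> kNN -> community-detection stack at the
final-map resolution (0.85) and then scores markers by AUROC and ln
fold-change; prints agreement with the planted cell types.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from evmap.embed_cluster import normalize_log1p
from evmap.markers import find_markers
from evmap.qc import qc_overcluster
from evmap.synthetic import SimConfig, simulate_experiment

cfg = SimConfig(n_samples=1, nuclei_per_sample=1200, n_genes=800,
                n_de_genes=20, seed=1)
cm, truth = simulate_experiment(cfg)

labels = qc_overcluster(cm, resolution=0.85, seed=0)
ari = adjusted_rand_score(truth.nuclei["cell_type"], labels.labels)
print(f"clusters found: {labels.n_clusters}  adjusted Rand index vs truth: {ari:.3f}")

table = find_markers(normalize_log1p(cm), labels.labels,
                     gene_ids=list(cm.genes["gene_id"]))
print(table.groupby("cluster").head(3).to_string(index=False))
print("ARI near 1 means the community map reproduces the planted cell types; "
      "each cluster's top markers have AUC > 0.7 and ln fold-change > 1.")
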