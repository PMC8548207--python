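"""Bulk-count utilities: the RPM fold filter and miRNA composition summary.

Simulates a two-group bulk experiment with 10 planted four-fold features and
a pooled miRNA table; prints which features the expressed-and-folded filter
keeps and the leading miRNA fractions.
"""

import numpy as np

from evmap.bulk_quant import fold_filter, mirna_fraction, rpm_normalize
from evmap.synthetic import simulate_bulk_table

means = {"tom": np.full(60, 120.0), "gfp": np.full(60, 120.0)}
means["gfp"][:10] *= 4
libs = {f"{g}_{i}": 2e6 for g in ("tom", "gfp") for i in range(3)}
tbl = simulate_bulk_table(60, means, dispersion=40.0, libsizes=libs, seed=0)

rpm = rpm_normalize(tbl)
mean_t = rpm[[c for c in tbl if c.startswith("tom")]].mean(axis=1)
mean_g = rpm[[c for c in tbl if c.startswith("gfp")]].mean(axis=1)
keep = fold_filter(mean_t, mean_g, min_rpm=25, min_fold=2)
print(f"kept {keep.sum()} of 60 features (10 planted at fold 4)")

rng = np.random.default_rng(1)
mirna = simulate_bulk_table(
    20, {"p": rng.lognormal(8, 2, 20)}, dispersion=20.0,
    libsizes={f"p_{i}": 1e6 for i in range(3)}, seed=2,
)
top = mirna_fraction(mirna, top_k=3)
print(top.to_string(index=False))
print("Fractions are percentages of the pooled signal; a handful of species "
      "dominating the pool mirrors the skewed composition typical of "
      "RBC-EV small-RNA cargo.")
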