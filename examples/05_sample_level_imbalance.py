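"""Compare overall allelic imbalance between samples and tissues.

Fits one symmetric beta-binomial dispersion parameter (alpha) per sample
across its genes.  Low alpha = widespread imbalance; high alpha = mostly
balanced expression.  Two synthetic tissues differing in true alpha show
up as separated distributions.
"""

import numpy as np
import pandas as pd

from aiqtl.scan import summarize_sample_alpha

rng = np.random.default_rng(0)
rows = []
for tissue, alpha in [("whole_blood", 10.0), ("testis", 40.0)]:
    for s in range(15):
        sample = f"{tissue}_{s:02d}"
        total = rng.negative_binomial(100, 100 / 130, 80) + 2
        a = rng.binomial(total, rng.beta(alpha, alpha, 80))
        rows += [
            dict(sample_id=sample, gene_id=f"g{i}", a_count=ai, total_count=ti)
            for i, (ai, ti) in enumerate(zip(a, total))
        ]
counts = pd.DataFrame(rows)
meta = counts[["sample_id"]].drop_duplicates()
meta["tissue"] = meta["sample_id"].str.rsplit("_", n=1).str[0]
meta["age"] = rng.integers(25, 70, len(meta))

summary = summarize_sample_alpha(counts, meta)
print(summary.table.groupby("tissue")["alpha"].describe()[["count", "25%", "50%", "75%"]])
print()
print(summary.correlations[["group", "covariate", "kind", "statistic", "p_holm"]]
      .to_string(index=False))
# the per-tissue alpha distributions separate in the right order, and the
# age covariate (independent of alpha here) stays non-significant after
# Holm correction.
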