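"""Model detection probability as a function of distance to the TSS.

Builds a synthetic scan table in which the true detection probability
decays with distance from the transcription start site, fits the
logistic regression, and predicts the detection-probability curve for a
strong eQTL (500 informative samples, median 30 reads, p = 1e-20).
"""

import numpy as np

from aiqtl.scan import fit_distance_logistic, predict_aiqtl_probability

# synthetic scan outcomes from a known decaying-detection model
rng = np.random.default_rng(0)
n = 600
dist = rng.integers(-900_000, 900_000, n)
import pandas as pd
from scipy.special import expit

table = pd.DataFrame(
    dict(
        gene_id=[f"g{i}" for i in range(n)],
        variant_id=[f"v{i}" for i in range(n)],
        tss_distance=dist,
        n_informative_samples=rng.integers(100, 600, n),
        median_reads=rng.uniform(10, 50, n),
        maf=rng.uniform(0.05, 0.5, n),
        eqtl_log10_p=rng.uniform(-30, -5, n),
        p_value=0.5,
    )
)
eta = 0.5 - 0.004 * np.abs(dist) / 1e3 + 0.003 * table.n_informative_samples \
    - 0.04 * table.eqtl_log10_p - 2.0
table["detected"] = rng.random(n) < expit(eta)

model = fit_distance_logistic(table)
print(model.summary.round(4))

covariates = dict(n_informative_samples=500, median_reads=30.0,
                  maf=0.05, eqtl_log10_p=-20.0)
curve = predict_aiqtl_probability(model, covariates,
                                  distance_grid=[0, -100e3, -250e3, -500e3, -1e6])
print(curve.to_string(index=False))
# the fitted upstream/downstream slopes are negative: the further an eQTL
# sits from the TSS, the lower the probability its effect is confirmed as
# allelic imbalance, i.e. as genuinely cis-acting.
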