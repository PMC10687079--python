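"""Associating salient connectivity features with symptom severity.

Simulates severity scores correlated with one connectivity feature and runs
the Spearman + Benjamini-Yekutieli association analysis the biomarker stage
feeds into.
"""

import numpy as np

from connharm import symptom_association

rng = np.random.default_rng(0)
n = 38   # a small clinical cohort
fc = rng.normal(0.3, 0.15, size=(n, 3))            # three candidate FC features
severity = np.column_stack([
    60 - 40 * fc[:, 0] + rng.normal(0, 3, n),      # total score tracks feature 0
    rng.normal(45, 8, n),                          # a scale with no association
])

table = symptom_association(fc, severity, q=0.05,
                            feature_names=["roi7-roi3", "roi9-roi2", "roi5-roi1"],
                            scale_names=["total", "positive"])
print(table[["feature", "scale", "n", "rho", "p", "significant"]].round(4).to_string(index=False))
print("\nSpearman rho per (feature, scale); 'significant' applies the")
print("Benjamini-Yekutieli false-discovery control at q = 0.05 across all tests.")
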