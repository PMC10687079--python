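"""From ROI time series to model-ready connectivity features.

Draws block-correlated ROI time series for one subject, computes the Pearson
FC matrix, applies the Fisher z-transform, and vectorises the strict lower
triangle — the feature layout every downstream stage indexes into.
"""

import numpy as np

from connharm import (compute_fc_matrix, fisher_transform, n_features,
                      vectorize_lower_triangle)
from connharm.synthetic import generate_roi_timeseries

ts = generate_roi_timeseries(n_rois=12, n_timepoints=500, block_size=4,
                             within_r=0.5, seed=0)[0]
print(f"time series: {ts.values.shape[0]} timepoints x {ts.values.shape[1]} ROIs")

fc = compute_fc_matrix(ts)
within = fc.values[1, 0]       # same block -> target correlation 0.5
across = fc.values[5, 0]       # different blocks -> target 0
print(f"within-block r = {within:.3f} (target 0.5), "
      f"across-block r = {across:.3f} (target 0)")

z = fisher_transform(fc)
print(f"Fisher z of within-block pair = {z.values[1, 0]:.3f} "
      f"(arctanh of {within:.3f})")

vec = vectorize_lower_triangle(z)
print(f"feature vector length = {vec.size} = R(R-1)/2 for R=12")
print(f"a 264-ROI parcellation would give {n_features(264)} features")
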