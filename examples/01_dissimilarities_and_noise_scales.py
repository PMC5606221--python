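"""Compute dissimilarities and local noise scales for a microbiome-like table.

Builds a synthetic presence/absence gradient (species entering and
leaving along a depth-like axis), computes Jaccard distances, and
estimates the KNN-based relative noise scales that tell the model which
dissimilarities to trust.
"""

import numpy as np

from buds import (GradientParams, generate_gradient, jaccard_matrix,
                  knn_variance_scales, rank_transform)

g = generate_gradient(GradientParams(n=40, p=150, mode="counts", seed=1))
D = jaccard_matrix(g.X)
S = knn_variance_scales(D, K=10)

off = ~np.eye(D.n, dtype=bool)
print(f"samples: {D.n}, features: {g.X.n_features}")
print(f"Jaccard distances: min {D.values[off].min():.3f}, "
      f"median {np.median(D.values[off]):.3f}, max {D.values[off].max():.3f}")
print(f"noise scales s2_ij: min {S.values[off].min():.3f}, "
      f"max {S.values[off].max():.3f}, mean {S.values[off].mean():.3f}")
# The mean of s2_ij is 1 by construction: scales are relative, the
# overall noise magnitude is the model's sigma_eps.

Dr = rank_transform(D)
print(f"after rank transform: min {Dr.values[off].min():.3f}, "
      f"max {Dr.values[off].max():.3f} (ordinal spread over (0, 1])")
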