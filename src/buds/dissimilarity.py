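"""Dissimilarity metrics, the ordinal rank transform, and KNN noise scales.

Three metrics cover the common input types: Jaccard distance on
presence/absence (16S / microbiome counts), the scaled Pearson correlation
distance ``(1 - rho)/2`` on continuous profiles (log-expression), and the
normalized L1 (Hamming fraction) on binary vote vectors.  The rank
transform ``d~ = 1 - sqrt(1 - rank(d)/m)`` spreads dissimilarities that
are concentrated away from zero while preserving their order.

Noise scales: for each pair (i, j) the empirical variance of the
distances from x_i to the K nearest neighbors of x_j and from x_j to the
K nearest neighbors of x_i (excluding each other) estimates how noisy
d_ij is; mean-normalizing these variances yields the relative scale
factors s2_ij that enter the Gamma likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import distance as ssd
from scipy.stats import rankdata

from .datatypes import DataMatrix, DissimilarityMatrix, NoiseScales

__all__ = [
    "jaccard_matrix",
    "correlation_distance_matrix",
    "kernel_l1_matrix",
    "rank_transform",
    "knn_variance_scales",
    "compute_dissimilarity",
]

#: floor for KNN-set variances, as a fraction of (mean off-diagonal d)^2
EPS_VAR_FACTOR = 1e-6


def jaccard_matrix(X: DataMatrix) -> DissimilarityMatrix:
    """Jaccard distance on presence/absence: 1 - |A & B| / |A | B|.

    Counts are thresholded at > 0 first.  A pair of samples with two
    empty supports gets distance 0 by convention.
    """
    if X.kind not in ("counts", "binary"):
        raise ValueError("Jaccard distance requires counts or binary data")
    B = (X.values > 0)
    if not B.any():
        raise ValueError("all-zero data matrix carries no presence/absence information")
    # scipy's jaccard on booleans is exactly 1 - |intersection|/|union|,
    # with the 0/0 pair defined as 0
    d = ssd.squareform(ssd.pdist(B.T, metric="jaccard"))
    return DissimilarityMatrix(values=d, sample_ids=X.sample_ids, metric_tag="jaccard")


def correlation_distance_matrix(X: DataMatrix) -> DissimilarityMatrix:
    """Scaled correlation distance d_ij = (1 - rho(x_i, x_j)) / 2 in [0, 1]."""
    sd = X.values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"sample {X.sample_ids[bad[0]]!r} is constant; "
            "correlation distance is undefined"
        )
    # scipy's 'correlation' metric is 1 - rho
    d = ssd.squareform(ssd.pdist(X.values.T, metric="correlation")) / 2.0
    return DissimilarityMatrix(
        values=np.clip(d, 0.0, 1.0), sample_ids=X.sample_ids, metric_tag="correlation"
    )


def kernel_l1_matrix(X: DataMatrix) -> DissimilarityMatrix:
    """Normalized L1 on binary vectors: the fraction of disagreeing coordinates.

    The metric_tag records the normalized-L1/Hamming reading of "kernel L1".
    """
    if X.kind != "binary":
        raise ValueError("kernel L1 distance requires binary data")
    d = ssd.squareform(ssd.pdist(X.values.T, metric="hamming"))
    return DissimilarityMatrix(
        values=d, sample_ids=X.sample_ids, metric_tag="kernel-l1(hamming)"
    )


def rank_transform(D: DissimilarityMatrix) -> DissimilarityMatrix:
    """Ordinal transform d~_ij = 1 - sqrt(1 - rank(d_ij)/m), m = n(n-1)/2.

    Ranks are computed over the upper-triangle values only (average ranks
    for ties), so the transform is strictly increasing in rank and maps
    the largest dissimilarity to 1.
    """
    n = D.n
    iu = np.triu_indices(n, k=1)
    vals = D.values[iu]
    m = vals.size
    r = rankdata(vals, method="average")
    transformed = 1.0 - np.sqrt(1.0 - r / m)
    out = np.zeros_like(D.values)
    out[iu] = transformed
    out = out + out.T
    return DissimilarityMatrix(
        values=out,
        sample_ids=D.sample_ids,
        metric_tag=D.metric_tag + "+rank",
        rank_transformed=True,
    )


def _knn_sets(d: np.ndarray, K: int) -> np.ndarray:
    """Indices of the K nearest neighbors of each point (self excluded).

    Ties at the K-th neighbor break by sample index (stable sort on
    distance), making the neighborhoods deterministic.
    """
    n = d.shape[0]
    nbrs = np.empty((n, K), dtype=int)
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        order = order[order != i]
        nbrs[i] = order[:K]
    return nbrs


def knn_variance_scales(D: DissimilarityMatrix, K: int) -> NoiseScales:
    """Mean-normalized local variance estimates s2_ij for each dissimilarity.

    For pair (i, j), pool the distances from x_i to the K nearest
    neighbors of x_j (minus x_i itself) and from x_j to the K nearest
    neighbors of x_i (minus x_j); the unbiased variance of that pool is
    the raw estimate s^2(d_ij).  Raw estimates are floored at
    ``EPS_VAR_FACTOR * mean(d)^2`` (degenerate equidistant data would
    otherwise give zero scales) and divided by their off-diagonal mean.
    """
    n = D.n
    if not (2 <= K <= n - 2):
        raise ValueError(f"K must satisfy 2 <= K <= n - 2 (n={n}, K={K})")
    d = D.values
    nbrs = _knn_sets(d, K)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = d[i, nbrs[j][nbrs[j] != i]]
            b = d[j, nbrs[i][nbrs[i] != j]]
            pool = np.concatenate([a, b])
            if pool.size < 2:
                raise ValueError(f"too few neighbor distances for pair ({i}, {j})")
            v = pool.var(ddof=1)
            raw[i, j] = raw[j, i] = v
    off = ~np.eye(n, dtype=bool)
    floor = EPS_VAR_FACTOR * d[off].mean() ** 2
    floored = np.maximum(raw, floor)
    scales = floored / floored[off].mean()
    np.fill_diagonal(scales, 1.0)
    return NoiseScales(values=scales, K=K, raw_variances=raw)


_METRICS = {
    "jaccard": jaccard_matrix,
    "correlation": correlation_distance_matrix,
    "kernel-l1": kernel_l1_matrix,
}


def compute_dissimilarity(
    X: DataMatrix, metric: str, rank: bool = False
) -> DissimilarityMatrix:
    """Dispatch to one of the named metrics, optionally rank-transforming."""
    try:
        D = _METRICS[metric](X)
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    return rank_transform(D) if rank else D
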