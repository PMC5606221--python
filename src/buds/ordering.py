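"""Analysis products built on the latent ordering.

Seriation reorders a heatmap: columns by ascending tau, rows by the
feature score z_k = x~_k . tau where x~_k is the k-th row of the
column-normalized data matrix — z_k is the mean latent location where
feature k "resides", so sequentially appearing features form a banded or
triangular matrix.  Covariate association checks whether an external
variable tracks the recovered gradient (Spearman rank correlation), and
feature trends smooth individual features against tau with LOESS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import DataMatrix

__all__ = [
    "SeriationResult",
    "FeatureTrend",
    "seriate",
    "covariate_association",
    "feature_trend",
]


@dataclass
class SeriationResult:
    row_order: np.ndarray     # permutation of feature indices
    col_order: np.ndarray     # permutation of sample indices
    z: np.ndarray             # feature scores, one per original feature


@dataclass
class FeatureTrend:
    feature_id: str
    grid: np.ndarray
    fitted: np.ndarray
    span: float

    def __post_init__(self):
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("trend grid must be strictly increasing")
        if not np.all(np.isfinite(self.fitted)):
            raise ValueError("fitted trend contains non-finite values")


def seriate(X: DataMatrix, tau_hat: np.ndarray,
            normalization: str = "unit-sum") -> SeriationResult:
    """Order heatmap rows and columns by the latent gradient.

    ``normalization`` is "unit-sum" (columns scaled to sum 1, the
    compositional view) or "unit-norm" (columns scaled to Euclidean
    norm 1).  The feature score is the weighted mean
    z_k = (x~_k . tau) / (x~_k . 1) — the expected latent location where
    feature k resides — so a feature present only in the sample with the
    largest tau scores exactly max(tau).  Features with an all-zero row
    carry no location information and are placed last.  Row score ties
    break by feature index.
    """
    tau_hat = np.asarray(tau_hat, dtype=float)
    if tau_hat.shape != (X.n_samples,):
        raise ValueError("tau_hat must have one entry per sample")
    V = X.values
    if normalization == "unit-sum":
        colsum = V.sum(axis=0)
        bad = np.flatnonzero(colsum == 0)
        if bad.size:
            raise ValueError(
                f"sample {X.sample_ids[bad[0]]!r} has zero column sum; "
                "cannot column-normalize"
            )
        Xn = V / colsum
    elif normalization == "unit-norm":
        norms = np.linalg.norm(V, axis=0)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"sample {X.sample_ids[bad[0]]!r} has zero norm")
        Xn = V / norms
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    weights = Xn.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(weights != 0, (Xn @ tau_hat) / weights, np.nan)
    col_order = np.argsort(tau_hat, kind="stable")
    sort_key = np.where(np.isnan(z), np.inf, z)  # uninformative rows last
    row_order = np.lexsort((np.arange(z.size), sort_key))
    return SeriationResult(row_order=row_order, col_order=col_order, z=z)


def covariate_association(tau_hat: np.ndarray, covariate: np.ndarray):
    """Spearman correlation between the ordering and a sample covariate.

    Returns ``(rho, table)`` where the table pairs the tau ranks with the
    covariate ranks (average ranks for ties) for a rank-rank scatter.
    """
    tau_hat = np.asarray(tau_hat, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != tau_hat.shape:
        raise ValueError("covariate must have one value per sample")
    if np.all(covariate == covariate[0]):
        raise ValueError("constant covariate has no rank association")
    rho = float(spearmanr(tau_hat, covariate).statistic)
    table = pd.DataFrame({
        "tau_hat": tau_hat,
        "tau_rank": rankdata(tau_hat, method="average"),
        "covariate": covariate,
        "covariate_rank": rankdata(covariate, method="average"),
    })
    return rho, table


def feature_trend(x_k: np.ndarray, tau_hat: np.ndarray, span: float = 0.5,
                  feature_id: str = "feature") -> FeatureTrend:
    """LOESS-smoothed trend of one feature along the latent ordering.

    Local linear regression (tricube weights, no robustness iterations,
    hence deterministic) evaluated on the sorted unique tau values.
    """
    x_k = np.asarray(x_k, dtype=float)
    tau_hat = np.asarray(tau_hat, dtype=float)
    if x_k.shape != tau_hat.shape:
        raise ValueError("feature vector and tau_hat must be the same length")
    if x_k.size < 5:
        raise ValueError("need at least 5 samples for a smoothed trend")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must lie in (0, 1]")
    grid = np.unique(tau_hat)
    fitted = lowess(x_k, tau_hat, frac=span, it=0, xvals=grid)
    return FeatureTrend(feature_id=feature_id, grid=grid,
                        fitted=np.asarray(fitted, dtype=float), span=span)
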