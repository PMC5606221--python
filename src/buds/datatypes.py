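"""Core containers: data matrices, dissimilarity matrices and noise scales.

The observed data is a features x samples matrix ``X`` (counts,
log-expression or binary votes).  Everything downstream of the metrics
operates on a symmetric ``n x n`` dissimilarity matrix ``D`` with zero
diagonal, optionally accompanied by mean-normalized relative noise scales
``s2_ij`` that encode how reliable each dissimilarity is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "DissimilarityMatrix",
    "NoiseScales",
    "read_data_matrix",
    "read_dissimilarity",
    "write_dissimilarity",
]


def _as_labels(labels: Sequence | None, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"expected {n} {prefix} labels, got {len(labels)}")
    return labels


@dataclass
class DataMatrix:
    """Features x samples matrix with row/column labels.

    ``kind`` is one of ``{"counts", "continuous", "binary"}`` and controls
    which dissimilarity metrics accept the matrix.
    """

    values: np.ndarray
    feature_ids: list[str] = None
    sample_ids: list[str] = None
    kind: str = "continuous"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix values must be 2-D (features x samples)")
        p, n = self.values.shape
        if n < 4:
            raise ValueError(f"need at least 4 samples, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DataMatrix contains missing or non-finite entries")
        if self.kind not in ("counts", "continuous", "binary"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary DataMatrix must contain only 0/1 entries")
        self.feature_ids = _as_labels(self.feature_ids, p, "f")
        self.sample_ids = _as_labels(self.sample_ids, n, "s")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative n x n matrix with zero diagonal."""

    values: np.ndarray
    sample_ids: list[str] = None
    metric_tag: str = "precomputed"
    rank_transformed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValueError("dissimilarities must be nonnegative")
        # enforce exact symmetry / zero diagonal after the tolerance checks
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)
        if self.rank_transformed and self.values.max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("rank-transformed dissimilarities must lie in [0, 1]")
        self.sample_ids = _as_labels(self.sample_ids, n, "s")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class NoiseScales:
    """Relative noise scales s2_ij for each dissimilarity.

    Off-diagonal entries are mean-normalized to 1, so sigma_eps^2 in the
    model carries the overall noise magnitude and ``values`` only the
    relative pattern.  ``raw_variances`` keeps the unnormalized KNN-set
    variance estimates for inspection.
    """

    values: np.ndarray
    K: int = 0
    raw_variances: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("noise scales must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("noise scales must be symmetric")
        off = ~np.eye(n, dtype=bool)
        if np.any(self.values[off] <= 0):
            raise ValueError("noise scales must be strictly positive")
        mean_off = self.values[off].mean()
        if abs(mean_off - 1.0) > 1e-9:
            raise ValueError(
                f"off-diagonal noise scales must average 1 (got {mean_off:.6g})"
            )

    @classmethod
    def uniform(cls, n: int) -> "NoiseScales":
        """Homoscedastic scales: s2_ij = 1 for every pair."""
        v = np.ones((n, n))
        return cls(values=v, K=0, raw_variances=None)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_data_matrix(path, kind: str = "continuous", transpose: bool = False) -> DataMatrix:
    """Read a features x samples table (first column = feature ids, header = sample ids)."""
    df = _read_table(path)
    if transpose:
        df = df.T
    return DataMatrix(
        values=df.to_numpy(dtype=float),
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        kind=kind,
    )


def read_dissimilarity(path, metric_tag: str = "precomputed") -> DissimilarityMatrix:
    """Read a square dissimilarity table with matching header and row names."""
    df = _read_table(path)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("dissimilarity table row names must match column names")
    return DissimilarityMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=list(df.columns),
        metric_tag=metric_tag,
    )


def write_dissimilarity(D: DissimilarityMatrix, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(D.values, index=D.sample_ids, columns=D.sample_ids).to_csv(path, sep=sep)
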