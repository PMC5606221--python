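"""Low-dimensional geometry of the ordering with uncertainty.

Classical scaling (PCoA) and t-SNE embed the observed dissimilarities;
posterior draws of tau supply trajectory paths through the embedding.
For uncertainty visualization the model is run generatively: each
posterior draw yields a latent distance matrix and a Gamma-noised
dissimilarity matrix; the stack of these matrices (a data cube) is
registered by DiSTATIS, a three-way metric MDS whose compromise space
carries a cloud of projected positions per sample.  Kernel density
estimates over those clouds give overall density fields and per-sample
highest-density confidence contours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.stats import gaussian_kde, spearmanr

from .datatypes import DissimilarityMatrix, NoiseScales
from .model import gamma_shape_rate

if TYPE_CHECKING:  # pragma: no cover
    from .inference import PosteriorSamples

__all__ = [
    "Embedding",
    "DissimilarityCube",
    "DistatisResult",
    "DensityField",
    "pcoa",
    "tsne_embed",
    "trajectory_paths",
    "sample_dissimilarity_cube",
    "distatis",
    "density_and_contours",
]


@dataclass
class Embedding:
    coords: np.ndarray            # (n, k)
    eigenvalues: np.ndarray | None
    pct_variance: np.ndarray | None
    method_tag: str


@dataclass
class DissimilarityCube:
    """t posterior dissimilarity matrices over the same n samples."""

    slices: np.ndarray            # (t, n, n)
    draw_ids: np.ndarray
    seed: int

    @property
    def t(self) -> int:
        return self.slices.shape[0]

    @property
    def n(self) -> int:
        return self.slices.shape[1]


@dataclass
class DistatisResult:
    consensus: np.ndarray         # (n, k)
    slice_projections: np.ndarray  # (t, n, k)
    alpha: np.ndarray             # (t,)
    eigenvalues: np.ndarray       # (k,)
    normalization: str = "leading-eigenvalue"


@dataclass
class ContourSet:
    """Highest-density contours for a single sample's projection cloud."""

    sample_index: int
    levels: list
    polylines: dict               # level -> list of (m, 2) arrays
    areas: dict                   # level -> HDR area on the grid
    degenerate: bool = False
    center: np.ndarray | None = None


@dataclass
class DensityField:
    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray           # (len(grid_y), len(grid_x))
    per_point_contours: list      # list of ContourSet
    bandwidth: tuple = ()
    bandwidth_rule: str = "scott"

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.grid_x, axis=1),
                                  self.grid_y))


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def _fix_signs(coords: np.ndarray, orient_by: np.ndarray | None) -> np.ndarray:
    """Deterministic axis signs.

    With ``orient_by`` (e.g. tau_hat): flip each axis so the sample with
    the smallest reference value has a coordinate <= the largest's.
    Otherwise flip so the entry of largest magnitude on each axis is
    positive.
    """
    coords = coords.copy()
    for a in range(coords.shape[1]):
        col = coords[:, a]
        if orient_by is not None:
            lo, hi = int(np.argmin(orient_by)), int(np.argmax(orient_by))
            if col[lo] > col[hi]:
                coords[:, a] = -col
        else:
            k = int(np.argmax(np.abs(col)))
            if col[k] < 0:
                coords[:, a] = -col
    return coords


def pcoa(D: DissimilarityMatrix, k: int = 2,
         orient_by: np.ndarray | None = None) -> Embedding:
    """Classical scaling of a dissimilarity matrix.

    Double-centers -1/2 J D^(2) J, eigendecomposes, and returns the top-k
    eigenvectors scaled by sqrt(eigenvalue).  Percent variance is taken
    over the positive eigenvalues only.  If fewer than k positive
    eigenvalues exist, k shrinks with a warning.
    """
    n = D.n
    if k > n - 1:
        raise ValueError("k must be at most n - 1")
    D2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0.0) * 1e-12
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalues; input is degenerate")
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; shrinking k from {k}")
        k = n_pos
    lam = evals[:k]
    coords = evecs[:, :k] * np.sqrt(lam)
    coords = _fix_signs(coords, orient_by)
    pct = 100.0 * lam / evals[pos].sum()
    return Embedding(coords=coords, eigenvalues=lam, pct_variance=pct,
                     method_tag="pcoa")


def tsne_embed(D: DissimilarityMatrix, k: int = 2, seed: int = 0,
               perplexity: float = 10.0) -> Embedding:
    """t-SNE on a precomputed dissimilarity matrix; reproducible per seed."""
    from sklearn.manifold import TSNE

    n = D.n
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity must be below (n - 1)/3 = {(n - 1) / 3:.1f}, got {perplexity}"
        )
    ts = TSNE(
        n_components=k,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
    )
    coords = ts.fit_transform(D.values)
    return Embedding(coords=coords, eigenvalues=None, pct_variance=None,
                     method_tag="tsne")


# ---------------------------------------------------------------------------
# posterior trajectories and the dissimilarity cube
# ---------------------------------------------------------------------------

def trajectory_paths(samples: "PosteriorSamples", n_paths: int = 50,
                     n_highlight: int = 10):
    """Sample orderings from posterior draws, plus a mode path.

    Returns ``(paths, mode_path)``: ``paths`` holds, for ``n_paths``
    evenly spaced draws, the permutation of samples by ascending tau in
    that draw; ``mode_path`` connects the samples whose posterior-mean
    tau values are nearest to an evenly spaced grid on [0, 1] of size
    ``n_highlight`` (duplicates dropped, grid order kept).
    """
    T = samples.T
    if n_paths > T:
        warnings.warn(f"only {T} draws available; shrinking n_paths from {n_paths}")
        n_paths = T
    draw_idx = np.linspace(0, T - 1, n_paths).astype(int)
    paths = [np.argsort(samples.tau[t], kind="stable") for t in draw_idx]

    tau_hat = samples.tau.mean(axis=0)
    grid = np.linspace(0.0, 1.0, n_highlight)
    picked = []
    for g in grid:
        i = int(np.argmin(np.abs(tau_hat - g)))
        if i not in picked:
            picked.append(i)
    return paths, np.asarray(picked, dtype=int)


def sample_dissimilarity_cube(samples: "PosteriorSamples", S: NoiseScales,
                              t: int = 50, seed: int = 0) -> DissimilarityCube:
    """Generate t posterior dissimilarity matrices from the fitted model.

    For each selected draw, the latent distances delta*_ij = b + rho*|tau_i
    - tau_j| seed independent Gamma variables with variance s2_ij *
    sigma_eps^2 on the upper triangle, which is then mirrored.
    """
    if t > samples.T:
        raise ValueError(f"requested {t} slices but only {samples.T} draws exist")
    n = samples.n
    if S.n != n:
        raise ValueError("noise scales must be conformable with the draws")
    rng = np.random.default_rng(seed)
    draw_ids = np.linspace(0, samples.T - 1, t).astype(int)
    iu = np.triu_indices(n, k=1)
    s2 = S.values[iu]
    slices = np.zeros((t, n, n))
    for out, td in enumerate(draw_ids):
        tau = samples.tau[td]
        delta = samples.b[td] + samples.rho[td] * np.abs(tau[iu[0]] - tau[iu[1]])
        delta = np.maximum(delta, 1e-6)
        shape, rate = gamma_shape_rate(delta, s2 * samples.sigma_eps[td] ** 2)
        vals = np.maximum(rng.gamma(shape, 1.0 / rate), 1e-12)
        M = np.zeros((n, n))
        M[iu] = vals
        slices[out] = M + M.T
    return DissimilarityCube(slices=slices, draw_ids=draw_ids, seed=seed)


# ---------------------------------------------------------------------------
# DiSTATIS
# ---------------------------------------------------------------------------

def _cross_product(Dmat: np.ndarray) -> np.ndarray:
    n = Dmat.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Smat = -0.5 * J @ (Dmat**2) @ J
    return (Smat + Smat.T) / 2.0


def distatis(cube: DissimilarityCube, k: int = 2,
             orient_by: np.ndarray | None = None,
             normalization: str = "leading-eigenvalue") -> DistatisResult:
    """Three-way MDS registration of a stack of dissimilarity matrices.

    Each slice's double-centered cross-product is normalized by its
    leading eigenvalue (the canonical choice; ``normalization="trace"``
    divides by the trace instead); slices are weighted by the leading
    eigenvector of their RV-coefficient similarity matrix; the weighted
    compromise is eigendecomposed for consensus coordinates, and every
    slice is projected into that space.
    """
    if cube.t < 2:
        raise ValueError("DiSTATIS needs at least 2 slices")
    if normalization not in ("leading-eigenvalue", "trace"):
        raise ValueError(f"unknown normalization {normalization!r}")
    mats = []
    kept = []
    for s in range(cube.t):
        Smat = _cross_product(cube.slices[s])
        lead = np.linalg.eigvalsh(Smat)[-1]
        if lead <= 0:
            warnings.warn(f"slice {s} has non-positive leading eigenvalue; dropped")
            continue
        denom = lead if normalization == "leading-eigenvalue" else np.trace(Smat)
        mats.append(Smat / denom)
        kept.append(s)
    t = len(mats)
    if t < 2:
        raise ValueError("fewer than 2 usable slices after dropping degenerate ones")

    C = np.empty((t, t))
    traces = [np.sqrt(np.sum(M * M)) for M in mats]
    for a in range(t):
        for b in range(a, t):
            rv = np.sum(mats[a] * mats[b]) / (traces[a] * traces[b])
            C[a, b] = C[b, a] = rv
    evals_c, evecs_c = np.linalg.eigh(C)
    alpha = evecs_c[:, -1]
    if alpha.sum() < 0:
        alpha = -alpha
    alpha = np.clip(alpha, 0.0, None)
    alpha = alpha / alpha.sum()

    S_plus = sum(a * M for a, M in zip(alpha, mats))
    S_plus = (S_plus + S_plus.T) / 2.0
    evals, evecs = np.linalg.eigh(S_plus)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int(np.sum(evals > max(evals.max(), 0.0) * 1e-12))
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(f"compromise has only {n_pos} positive eigenvalues; k -> {k_eff}")
    lam = evals[:k_eff]
    V = evecs[:, :k_eff]
    consensus = V * np.sqrt(lam)
    # fix signs once on the consensus, then project slices with the same V
    fixed = _fix_signs(consensus, orient_by)
    flip = np.sign(np.sum(fixed * consensus, axis=0))
    V = V * flip
    consensus = fixed
    proj = np.stack([M @ V / np.sqrt(lam) for M in mats])
    return DistatisResult(
        consensus=consensus,
        slice_projections=proj,
        alpha=alpha,
        eigenvalues=lam,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# density fields and confidence contours
# ---------------------------------------------------------------------------

def _hdr_threshold(density: np.ndarray, cell_area: float, mass: float) -> float:
    """Density level whose superlevel set holds ``mass`` probability."""
    flat = np.sort(density.ravel())[::-1]
    csum = np.cumsum(flat) * cell_area
    total = csum[-1]
    idx = int(np.searchsorted(csum, mass * total))
    idx = min(idx, flat.size - 1)
    return float(flat[idx])


def density_and_contours(
    result: DistatisResult,
    selected: Sequence[int] = (),
    levels: Sequence[float] = (0.5, 0.8, 0.95),
    grid_size: int = 128,
) -> DensityField:
    """KDE density cloud over all slice projections plus per-sample contours.

    The overall field pools every projected position (t slices x n
    samples).  For each selected sample, a KDE over its t projected
    positions yields highest-density contours at the requested
    probability levels; contour polylines are extracted from the grid.
    Scott's rule sets the bandwidth, recorded in the output.
    """
    from skimage import measure

    proj = result.slice_projections
    if proj.shape[2] != 2:
        raise ValueError("density fields require k = 2 projections")
    t = proj.shape[0]
    pooled = proj.reshape(-1, 2).T   # (2, t*n)

    kde = gaussian_kde(pooled, bw_method="scott")
    bw = np.sqrt(np.diag(kde.covariance))
    pad = 4.0 * bw
    x0, x1 = pooled[0].min() - pad[0], pooled[0].max() + pad[0]
    y0, y1 = pooled[1].min() - pad[1], pooled[1].max() + pad[1]
    gx = np.linspace(x0, x1, grid_size)
    gy = np.linspace(y0, y1, grid_size)
    XX, YY = np.meshgrid(gx, gy)
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)

    contours = []
    for idx in selected:
        pts = proj[:, idx, :]        # (t, 2)
        if t < 10:
            raise ValueError("per-point contours need at least 10 cube slices")
        if np.allclose(pts.std(axis=0), 0.0):
            contours.append(ContourSet(
                sample_index=int(idx), levels=list(levels), polylines={},
                areas={lv: 0.0 for lv in levels}, degenerate=True,
                center=pts[0].copy(),
            ))
            continue
        try:
            kde_i = gaussian_kde(pts.T, bw_method="scott")
        except np.linalg.LinAlgError:
            # collinear cloud: jitter-free fallback marks it degenerate
            contours.append(ContourSet(
                sample_index=int(idx), levels=list(levels), polylines={},
                areas={lv: 0.0 for lv in levels}, degenerate=True,
                center=pts.mean(axis=0),
            ))
            continue
        bwi = np.sqrt(np.diag(kde_i.covariance))
        padi = 4.0 * bwi
        lx = np.linspace(pts[:, 0].min() - padi[0], pts[:, 0].max() + padi[0], 96)
        ly = np.linspace(pts[:, 1].min() - padi[1], pts[:, 1].max() + padi[1], 96)
        LX, LY = np.meshgrid(lx, ly)
        di = kde_i(np.vstack([LX.ravel(), LY.ravel()])).reshape(LX.shape)
        cell = (lx[1] - lx[0]) * (ly[1] - ly[0])
        polylines = {}
        areas = {}
        for lv in levels:
            c = _hdr_threshold(di, cell, lv)
            lines = measure.find_contours(di, c)
            polys = []
            for line in lines:
                # row/col indices -> data coordinates
                xs = np.interp(line[:, 1], np.arange(lx.size), lx)
                ys = np.interp(line[:, 0], np.arange(ly.size), ly)
                polys.append(np.column_stack([xs, ys]))
            polylines[lv] = polys
            areas[lv] = float(np.sum(di >= c) * cell)
        contours.append(ContourSet(
            sample_index=int(idx), levels=list(levels), polylines=polylines,
            areas=areas, degenerate=False, center=pts.mean(axis=0),
        ))

    return DensityField(
        grid_x=gx, grid_y=gy, density=dens,
        per_point_contours=contours,
        bandwidth=tuple(bw), bandwidth_rule="scott",
    )
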