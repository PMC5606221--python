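"""Gradient-structured synthetic data with known latent coordinates.

Two generators define the study conditions used throughout the tests:

``generate_gradient`` builds a features x samples matrix whose columns
vary along a planted 1-D gradient tau_true — unimodal Poisson species
responses (microbiome-like counts), smooth sigmoid kinetics with
Gaussian noise (expression-like), or thresholded logistic responses
(vote-like binary data).  Sampling density along the gradient follows a
Beta(a, b) law, so uneven coverage (and hence wider uncertainty in
sparse regions) can be planted deliberately.

``generate_model_draw`` samples dissimilarities directly from the BUDS
generative model (Gamma noise around b + rho*|tau_i - tau_j|); it is the
exact-model fixture for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import DataMatrix, DissimilarityMatrix

__all__ = ["GradientParams", "SyntheticGradient", "generate_gradient",
           "generate_model_draw"]


@dataclass
class GradientParams:
    """Conditions for a synthetic gradient dataset.

    density (a, b) are the Beta parameters of the tau sampling law;
    (1, 1) is uniform, (3, 1) concentrates samples near tau = 1 leaving
    the low end sparse.  ``response_width`` is the sd of the Gaussian
    response curve in counts mode (0.15 means each species spans roughly
    a third of the gradient).
    """

    n: int = 50
    p: int = 200
    mode: str = "counts"
    noise_sd: float = 0.1
    density: tuple = (1.0, 1.0)
    response_width: float = 0.15
    peak_height: tuple = (20.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("need n >= 10 samples")
        if self.p < 20:
            raise ValueError("need p >= 20 features")
        if self.mode not in ("counts", "continuous", "binary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.response_width <= 0 or self.noise_sd < 0:
            raise ValueError("invalid noise/width parameters")


@dataclass
class SyntheticGradient:
    X: DataMatrix
    tau_true: np.ndarray
    generator_params: GradientParams


def generate_gradient(params: GradientParams) -> SyntheticGradient:
    """Sample a gradient dataset; byte-identical per (params, seed)."""
    rng = np.random.default_rng(params.seed)
    n, p = params.n, params.p
    a, b = params.density
    tau = rng.beta(a, b, size=n)

    if params.mode == "counts":
        centers = np.linspace(0.0, 1.0, p)
        heights = rng.uniform(*params.peak_height, size=p)
        mu = heights[:, None] * np.exp(
            -((tau[None, :] - centers[:, None]) ** 2)
            / (2.0 * params.response_width**2)
        )
        V = rng.poisson(mu).astype(float)
        kind = "counts"
    elif params.mode == "continuous":
        centers = rng.uniform(0.0, 1.0, size=p)
        slopes = rng.uniform(5.0, 20.0, size=p)
        signs = rng.choice([-1.0, 1.0], size=p)
        amps = rng.uniform(1.0, 3.0, size=p)
        V = amps[:, None] / (
            1.0 + np.exp(-signs[:, None] * slopes[:, None]
                         * (tau[None, :] - centers[:, None]))
        )
        V = V + params.noise_sd * rng.standard_normal((p, n))
        kind = "continuous"
    else:  # binary
        centers = rng.uniform(0.0, 1.0, size=p)
        slopes = rng.uniform(5.0, 20.0, size=p)
        signs = rng.choice([-1.0, 1.0], size=p)
        prob = 1.0 / (
            1.0 + np.exp(-signs[:, None] * slopes[:, None]
                         * (tau[None, :] - centers[:, None]))
        )
        V = (rng.uniform(size=(p, n)) < prob).astype(float)
        kind = "binary"

    X = DataMatrix(values=V, kind=kind,
                   feature_ids=[f"f{k}" for k in range(p)],
                   sample_ids=[f"s{i}" for i in range(n)])
    return SyntheticGradient(X=X, tau_true=tau, generator_params=params)


def _scale_pattern(name: str, tau: np.ndarray) -> np.ndarray:
    n = tau.size
    if name == "uniform":
        s2 = np.ones((n, n))
    elif name == "dense-middle":
        # pairs whose midpoint sits mid-gradient are measured more precisely
        mid = (tau[:, None] + tau[None, :]) / 2.0
        s2 = 0.5 + 2.0 * (mid - 0.5) ** 2 * 4.0
    else:
        raise ValueError(f"unknown scale pattern {name!r}")
    off = ~np.eye(n, dtype=bool)
    s2 = s2 / s2[off].mean()
    np.fill_diagonal(s2, 1.0)
    return s2


def generate_model_draw(
    n: int = 50,
    b: float = 0.05,
    rho: float = 1.0,
    sigma_eps: float = 0.3,
    scale_pattern: str = "uniform",
    seed: int = 0,
    tau_beta: tuple = (1.0, 1.0),
):
    """Draw (D, tau_true, params_true) from the BUDS generative model.

    tau_true ~ Beta(tau_beta); D has independent Gamma entries with mean
    b + rho*|tau_i - tau_j| and variance s2_ij * sigma_eps^2 on the upper
    triangle, mirrored to a symmetric matrix.  Draws are floored at
    1e-12: with small means and sigma_eps ~ 0.3 the implied Gamma shape
    is tiny and the sampler can underflow to exactly 0, outside the
    likelihood's support.
    """
    if sigma_eps <= 0 or rho <= 0 or b < 0:
        raise ValueError("require sigma_eps > 0, rho > 0, b >= 0")
    rng = np.random.default_rng(seed)
    tau = rng.beta(*tau_beta, size=n)
    iu = np.triu_indices(n, k=1)
    delta = b + rho * np.abs(tau[iu[0]] - tau[iu[1]])
    if b == 0.0 and np.any(delta == 0.0):
        # exact ties give a zero Gamma mean; jitter tau and warn
        import warnings

        warnings.warn("tau ties with b = 0; jittering tau to keep delta positive")
        tau = np.clip(tau + 1e-9 * rng.standard_normal(n), 0.0, 1.0)
        delta = b + rho * np.abs(tau[iu[0]] - tau[iu[1]])
    s2 = _scale_pattern(scale_pattern, tau)[iu]
    var = s2 * sigma_eps**2
    shape = delta**2 / var
    rate = delta / var
    vals = np.maximum(rng.gamma(shape, 1.0 / rate), 1e-12)
    M = np.zeros((n, n))
    M[iu] = vals
    D = DissimilarityMatrix(values=M + M.T, metric_tag="model-draw")
    params_true = {"b": b, "rho": rho, "sigma_eps": sigma_eps,
                   "tau_beta": tau_beta, "scale_pattern": scale_pattern,
                   "seed": seed}
    return D, tau, params_true
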