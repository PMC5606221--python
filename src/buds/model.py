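"""The BUDS joint probability model.

Observed dissimilarities are modeled as Gamma random variables centered
at latent 1-D distances with heteroscedastic noise::

    d_ij | tau, b, rho, sigma_eps ~ Gamma(mu_ij, sigma_ij^2)
    mu_ij    = b + rho * |tau_i - tau_j|        (shift/scale transform)
    sigma_ij^2 = s2_ij * sigma_eps^2
    tau_i ~ Beta(alpha_tau, beta_tau)
    alpha_tau, beta_tau ~ Cauchy+(1, gamma_tau)
    rho ~ Cauchy+(1, gamma_rho);  b ~ Cauchy+(0, gamma_b)
    sigma_eps ~ Cauchy+(0, gamma_eps)

where Gamma(mu, sigma^2) denotes the mean/variance parameterization with
shape = mu^2/sigma^2 and rate = mu/sigma^2, and Cauchy+(c, g) is a Cauchy
located at c truncated to (0, inf).  The hierarchical Beta prior lets the
model adapt to uneven sampling density along the gradient.

``log_joint`` evaluates the full log density; ``log_joint_grad`` returns
its analytic gradient with respect to (tau, alpha_tau, beta_tau,
sigma_eps, b, rho), which drives the variational optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, digamma, gammaln

from .datatypes import DissimilarityMatrix, NoiseScales

__all__ = [
    "BUDSHyperParams",
    "BUDSParams",
    "gamma_shape_rate",
    "expected_dissimilarity",
    "half_cauchy_logpdf",
    "log_joint",
    "log_joint_grad",
]

MU_FLOOR = 1e-6


@dataclass
class BUDSHyperParams:
    """Half-Cauchy prior scales and model switches.

    All scales default to 2.5, a standard weakly informative choice for
    positive scale parameters.  ``use_shift_scale`` enables the
    mu = b + rho*|dtau| transform that reconciles the range of observed
    dissimilarities with distances on [0, 1].
    """

    gamma_tau: float = 2.5
    gamma_eps: float = 2.5
    gamma_b: float = 2.5
    gamma_rho: float = 2.5
    use_shift_scale: bool = True
    mu_floor: float = MU_FLOOR

    def __post_init__(self):
        for name in ("gamma_tau", "gamma_eps", "gamma_b", "gamma_rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_floor <= 0:
            raise ValueError("mu_floor must be positive")


@dataclass
class BUDSParams:
    """One realization of all latent variables."""

    tau: np.ndarray
    alpha_tau: float = 1.0
    beta_tau: float = 1.0
    sigma_eps: float = 0.1
    b: float = 0.0
    rho: float = 1.0

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)

    def in_support(self) -> bool:
        return bool(
            np.all((self.tau >= 0) & (self.tau <= 1))
            and self.alpha_tau > 0
            and self.beta_tau > 0
            and self.sigma_eps > 0
            and self.b >= 0
            and self.rho > 0
        )


def gamma_shape_rate(mu: float, var: float):
    """Convert a Gamma's (mean, variance) to (shape, rate).

    shape = mu^2/var, rate = mu/var, so shape/rate = mu and
    shape/rate^2 = var exactly.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(mu <= 0) or np.any(var <= 0):
        raise ValueError("gamma_shape_rate requires positive mean and variance")
    return mu * mu / var, mu / var


def expected_dissimilarity(params: BUDSParams, i: int, j: int,
                           hyper: BUDSHyperParams | None = None) -> float:
    """Model mean mu_ij = max(mu_floor, b + rho*|tau_i - tau_j|)."""
    if hyper is None:
        hyper = BUDSHyperParams()
    if i == j:
        raise ValueError("expected_dissimilarity requires i != j")
    dtau = abs(params.tau[i] - params.tau[j])
    mu = params.b + params.rho * dtau if hyper.use_shift_scale else dtau
    return max(hyper.mu_floor, mu)


def half_cauchy_logpdf(x: float, center: float, scale: float) -> float:
    """Log density of a Cauchy(center, scale) truncated to (0, inf).

    The truncation normalizer P(X > 0) = 1/2 + arctan(center/scale)/pi is
    included so densities are comparable across hyperparameter settings.
    """
    if x < 0:
        return -np.inf
    z = (x - center) / scale
    log_norm = np.log(0.5 + np.arctan(center / scale) / np.pi)
    return -np.log(np.pi * scale) - np.log1p(z * z) - log_norm


def _pair_arrays(params: BUDSParams, D: DissimilarityMatrix, S: NoiseScales):
    n = D.n
    if params.tau.shape != (n,):
        raise ValueError("tau length must match dissimilarity matrix size")
    if S.n != n:
        raise ValueError("noise scales must be conformable with D")
    iu = np.triu_indices(n, k=1)
    d = D.values[iu]
    if np.any(d <= 0):
        raise ValueError(
            "off-diagonal zero dissimilarity found (exact duplicate samples); "
            "deduplicate the samples or floor the dissimilarities before fitting"
        )
    s2 = S.values[iu]
    return iu, d, s2


def _gamma_terms(params: BUDSParams, hyper: BUDSHyperParams, iu, d, s2):
    ti, tj = params.tau[iu[0]], params.tau[iu[1]]
    dtau = np.abs(ti - tj)
    mu_raw = params.b + params.rho * dtau if hyper.use_shift_scale else dtau
    mu = np.maximum(hyper.mu_floor, mu_raw)
    v = s2 * params.sigma_eps**2
    alpha = mu * mu / v
    beta = mu / v
    ll = alpha * np.log(beta) - gammaln(alpha) + (alpha - 1.0) * np.log(d) - beta * d
    return dtau, mu_raw, mu, v, alpha, beta, ll


def log_joint(params: BUDSParams, D: DissimilarityMatrix, S: NoiseScales,
              hyper: BUDSHyperParams | None = None) -> float:
    """Full log joint density of (data, latent variables).

    Returns -inf (rather than raising) for parameter values outside the
    support, so samplers can call it freely; structurally invalid inputs
    (zero off-diagonal dissimilarities, shape mismatches) raise.
    """
    if hyper is None:
        hyper = BUDSHyperParams()
    iu, d, s2 = _pair_arrays(params, D, S)
    if not params.in_support():
        return -np.inf
    tau = params.tau
    if np.any(tau <= 0) or np.any(tau >= 1):
        # Beta density is 0 or infinite on the boundary for a != 1
        if params.alpha_tau != 1.0 or params.beta_tau != 1.0:
            return -np.inf
    *_, ll = _gamma_terms(params, hyper, iu, d, s2)
    total = float(ll.sum())

    with np.errstate(divide="ignore"):
        total += float(
            np.sum((params.alpha_tau - 1.0) * np.log(tau)
                   + (params.beta_tau - 1.0) * np.log1p(-tau))
            - tau.size * betaln(params.alpha_tau, params.beta_tau)
        )
    total += half_cauchy_logpdf(params.alpha_tau, 1.0, hyper.gamma_tau)
    total += half_cauchy_logpdf(params.beta_tau, 1.0, hyper.gamma_tau)
    total += half_cauchy_logpdf(params.sigma_eps, 0.0, hyper.gamma_eps)
    if hyper.use_shift_scale:
        total += half_cauchy_logpdf(params.b, 0.0, hyper.gamma_b)
        total += half_cauchy_logpdf(params.rho, 1.0, hyper.gamma_rho)
    return total


def _half_cauchy_dlogpdf(x: float, center: float, scale: float) -> float:
    z = x - center
    return -2.0 * z / (scale * scale + z * z)


def log_joint_grad(params: BUDSParams, D: DissimilarityMatrix, S: NoiseScales,
                   hyper: BUDSHyperParams | None = None):
    """Gradient of ``log_joint`` w.r.t. (tau, alpha_tau, beta_tau, sigma_eps, b, rho).

    Returns a dict of arrays/floats.  Valid only strictly inside the
    support (all tau in (0,1), positive scales).
    """
    if hyper is None:
        hyper = BUDSHyperParams()
    iu, d, s2 = _pair_arrays(params, D, S)
    tau = params.tau
    n = tau.size
    dtau, mu_raw, mu, v, alpha, beta, _ = _gamma_terms(params, hyper, iu, d, s2)

    # dlogGamma/dmu and dlogGamma/dv in the mean/variance parameterization
    g = np.log(beta) - digamma(alpha) + np.log(d)
    dl_dmu = (2.0 * mu / v) * g + (mu - d) / v
    dl_dv = -(mu / (v * v)) * (mu * g + (mu - d))
    active = mu_raw > hyper.mu_floor  # the floor clamps the gradient to zero

    sgn = np.sign(tau[iu[0]] - tau[iu[1]])
    coef = dl_dmu * active * (params.rho if hyper.use_shift_scale else 1.0) * sgn
    g_tau = np.zeros(n)
    np.add.at(g_tau, iu[0], coef)
    np.add.at(g_tau, iu[1], -coef)

    # Beta prior terms
    g_tau += (params.alpha_tau - 1.0) / tau - (params.beta_tau - 1.0) / (1.0 - tau)
    dig_ab = digamma(params.alpha_tau + params.beta_tau)
    g_alpha = float(np.sum(np.log(tau)) + n * (dig_ab - digamma(params.alpha_tau)))
    g_beta = float(np.sum(np.log1p(-tau)) + n * (dig_ab - digamma(params.beta_tau)))
    g_alpha += _half_cauchy_dlogpdf(params.alpha_tau, 1.0, hyper.gamma_tau)
    g_beta += _half_cauchy_dlogpdf(params.beta_tau, 1.0, hyper.gamma_tau)

    g_sigma = float(np.sum(dl_dv * 2.0 * s2 * params.sigma_eps))
    g_sigma += _half_cauchy_dlogpdf(params.sigma_eps, 0.0, hyper.gamma_eps)

    if hyper.use_shift_scale:
        g_b = float(np.sum(dl_dmu * active))
        g_b += _half_cauchy_dlogpdf(params.b, 0.0, hyper.gamma_b)
        g_rho = float(np.sum(dl_dmu * active * dtau))
        g_rho += _half_cauchy_dlogpdf(params.rho, 1.0, hyper.gamma_rho)
    else:
        g_b = 0.0
        g_rho = 0.0

    return {
        "tau": g_tau,
        "alpha_tau": g_alpha,
        "beta_tau": g_beta,
        "sigma_eps": g_sigma,
        "b": g_b,
        "rho": g_rho,
    }
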