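"""Mixing distributions and count kernels for zero-heavy crash panels.

The models in this package thicken the zero mass of a Negative Binomial (NB)
count kernel by multiplying its mean with a positive mixing variable drawn
from either a Lindley distribution (one parameter ``theta``) or a Generalized
Exponential (GE) distribution (scale ``omega``, shape ``v``).  This module
provides the densities, seeded samplers, and brute-force quadrature oracles
for the compound NB-Lindley and NB-GE probability mass functions.  The
oracles are the reference implementations against which the augmented MCMC
likelihoods are validated; they are deliberately written as direct numerical
integrals rather than series expansions.

All likelihood arithmetic is carried out in log space: ``Gamma(1/alpha + y)``
overflows for modest ``y`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

__all__ = [
    "LindleyParams",
    "GEParams",
    "NBKernelParams",
    "ParameterDomainError",
    "QuadratureError",
    "lindley_pdf",
    "lindley_logpdf",
    "lindley_mean",
    "lindley_var",
    "lindley_sample",
    "ge_pdf",
    "ge_logpdf",
    "ge_mean",
    "ge_sample",
    "nb_pmf",
    "nb_logpmf",
    "nb_sample",
    "nbl_pmf_oracle",
    "nbge_pmf_oracle",
]


class ParameterDomainError(ValueError):
    """A distribution parameter or argument is outside its domain."""


class QuadratureError(RuntimeError):
    """Adaptive quadrature failed to reach the requested tolerance."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)) or not np.all(np.asarray(value) > 0):
            raise ParameterDomainError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class LindleyParams:
    """Lindley distribution parameter ``theta`` (rate-like, > 0)."""

    theta: float

    def __post_init__(self) -> None:
        _require_positive(theta=self.theta)


@dataclass(frozen=True)
class GEParams:
    """Generalized Exponential parameters: scale ``omega`` and shape ``v``."""

    omega: float
    v: float

    def __post_init__(self) -> None:
        _require_positive(omega=self.omega, v=self.v)


@dataclass(frozen=True)
class NBKernelParams:
    """NB kernel in mean/overdispersion form: mean ``eta``, dispersion ``alpha``.

    The variance is ``eta + alpha * eta**2``; ``alpha -> 0`` recovers Poisson.
    """

    eta: float
    alpha: float

    def __post_init__(self) -> None:
        _require_positive(eta=self.eta, alpha=self.alpha)


# ---------------------------------------------------------------------------
# Lindley distribution
# ---------------------------------------------------------------------------

def lindley_logpdf(tau, theta):
    """Log density of the Lindley distribution, vectorized over ``tau``."""
    _require_positive(theta=theta)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ParameterDomainError("tau must be non-negative")
    return 2.0 * np.log(theta) - np.log1p(theta) + np.log1p(tau) - theta * tau


def lindley_pdf(tau, params: LindleyParams | float):
    """Lindley density theta^2/(theta+1) * (1+tau) * exp(-theta*tau)."""
    theta = params.theta if isinstance(params, LindleyParams) else float(params)
    return np.exp(lindley_logpdf(tau, theta))


def lindley_mean(theta: float) -> float:
    """Closed-form mean (theta+2) / (theta*(theta+1))."""
    _require_positive(theta=theta)
    return (theta + 2.0) / (theta * (theta + 1.0))


def lindley_var(theta: float) -> float:
    """Closed-form variance (theta^2 + 4*theta + 2) / (theta^2*(theta+1)^2)."""
    _require_positive(theta=theta)
    return (theta**2 + 4.0 * theta + 2.0) / (theta**2 * (theta + 1.0) ** 2)


def lindley_sample(params: LindleyParams | float, n: int, seed=None):
    """Draw ``n`` Lindley variates via the Bernoulli-Gamma mixture.

    chi ~ Bernoulli(1/(1+theta)) selects between Gamma(1, theta) and
    Gamma(2, theta) (shape, rate); marginally tau is Lindley(theta).
    """
    theta = params.theta if isinstance(params, LindleyParams) else float(params)
    _require_positive(theta=theta)
    if n < 1:
        raise ParameterDomainError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chi = rng.random(n) < 1.0 / (1.0 + theta)
    return rng.gamma(shape=1.0 + chi, scale=1.0 / theta)


# ---------------------------------------------------------------------------
# Generalized Exponential distribution
# ---------------------------------------------------------------------------

def ge_logpdf(lam, omega, v):
    """Log density of the GE distribution, vectorized over ``lam``."""
    _require_positive(omega=omega, v=v)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ParameterDomainError("lam must be non-negative")
    if v == 1.0:
        core = np.zeros_like(lam)
    else:
        with np.errstate(divide="ignore"):
            # (v-1)*log(1 - exp(-omega*lam)); -inf at lam=0 for v>1
            core = (v - 1.0) * np.log(-np.expm1(-omega * lam))
    return np.log(omega) + np.log(v) + core - omega * lam


def ge_pdf(lam, params: GEParams | tuple):
    """GE density omega*v*(1-exp(-omega*lam))^(v-1)*exp(-omega*lam)."""
    omega, v = (params.omega, params.v) if isinstance(params, GEParams) else params
    return np.exp(ge_logpdf(lam, omega, v))


def ge_mean(omega: float, v: float) -> float:
    """Closed-form mean (psi(v+1) - psi(1)) / omega."""
    _require_positive(omega=omega, v=v)
    return (special.digamma(v + 1.0) - special.digamma(1.0)) / omega


def ge_sample(params: GEParams | tuple, n: int, seed=None):
    """Draw GE variates by inversion: lam = -log(1 - U^(1/v)) / omega."""
    omega, v = (params.omega, params.v) if isinstance(params, GEParams) else params
    _require_positive(omega=omega, v=v)
    if n < 1:
        raise ParameterDomainError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    return -np.log1p(-np.power(u, 1.0 / v)) / omega


# ---------------------------------------------------------------------------
# Negative Binomial kernel
# ---------------------------------------------------------------------------

def nb_logpmf(y, eta, alpha):
    """Log pmf of NB with mean ``eta`` and overdispersion ``alpha``.

    Uses the size r = 1/alpha form:
    ``C(r+y-1, y) * (r/(r+eta))^r * (eta/(r+eta))^y`` computed in log space.
    Vectorized over any broadcastable combination of arguments.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ParameterDomainError("y must be non-negative")
    _require_positive(eta=np.asarray(eta), alpha=np.asarray(alpha))
    y = y.astype(float)
    r = 1.0 / np.asarray(alpha, dtype=float)
    eta = np.asarray(eta, dtype=float)
    log_denom = np.log(r + eta)
    return (
        special.gammaln(r + y)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * (np.log(r) - log_denom)
        + y * (np.log(eta) - log_denom)
    )


def nb_pmf(y, params: NBKernelParams | tuple):
    """NB probability mass at ``y`` for mean/overdispersion parameters."""
    eta, alpha = (params.eta, params.alpha) if isinstance(params, NBKernelParams) else params
    return np.exp(nb_logpmf(y, eta, alpha))


def nb_sample(eta, alpha, rng: np.random.Generator):
    """Draw NB counts by Gamma-Poisson mixing: Poisson(Gamma(1/alpha, alpha*eta))."""
    eta = np.asarray(eta, dtype=float)
    _require_positive(eta=eta, alpha=alpha)
    g = rng.gamma(shape=1.0 / alpha, scale=alpha * eta)
    return rng.poisson(g)


# ---------------------------------------------------------------------------
# Compound oracles (adaptive quadrature)
# ---------------------------------------------------------------------------

_QUAD_ABS_TOL = 1e-10


def _compound_quad(integrand, upper_scan, label):
    """Integrate ``integrand`` over [0, inf) with an explicit tail check.

    ``upper_scan`` is a sequence of candidate upper limits; the first whose
    integrand value falls below 1e-12 is used as the truncation point, and
    the remaining tail is integrated separately and added.
    """
    upper = None
    for u in upper_scan:
        if integrand(u) < 1e-12:
            upper = u
            break
    if upper is None:
        upper = upper_scan[-1]
    value, err = integrate.quad(integrand, 0.0, upper, epsabs=_QUAD_ABS_TOL, limit=200)
    tail, tail_err = integrate.quad(integrand, upper, np.inf, epsabs=_QUAD_ABS_TOL, limit=200)
    total_err = err + tail_err
    if not np.isfinite(value + tail) or total_err > max(1e-8, 1e-6 * abs(value + tail)):
        raise QuadratureError(
            f"{label}: quadrature error {total_err:.3e} exceeds tolerance (value {value + tail:.3e})"
        )
    return value + tail


def nbl_pmf_oracle(y: int, lam: float, theta: float, alpha: float) -> float:
    """NB-Lindley compound pmf by adaptive quadrature.

    ``P(Y=y) = int_0^inf NB(y; tau*lam, alpha) * Lindley(tau; theta) dtau``.
    This is the reference oracle for the NB-L likelihood and simulator.
    """
    _require_positive(lam=lam, theta=theta, alpha=alpha)
    if y < 0 or int(y) != y:
        raise ParameterDomainError("y must be a non-negative integer")

    def integrand(tau):
        if tau <= 0.0:
            # NB mean must be positive; the integrand vanishes at tau=0
            return 0.0
        return float(
            np.exp(nb_logpmf(y, tau * lam, alpha) + lindley_logpdf(tau, theta))
        )

    scan = [x / theta for x in (20.0, 50.0, 100.0, 400.0)]
    return _compound_quad(integrand, scan, "nbl_pmf_oracle")


def nbge_pmf_oracle(y: int, lam: float, params: GEParams | tuple, alpha: float) -> float:
    """NB-GE compound pmf by adaptive quadrature.

    ``P(Y=y) = int_0^inf NB(y; lam*Lam, alpha) * GE(Lam; omega, v) dLam``.
    """
    omega, v = (params.omega, params.v) if isinstance(params, GEParams) else params
    _require_positive(lam=lam, omega=omega, v=v, alpha=alpha)
    if y < 0 or int(y) != y:
        raise ParameterDomainError("y must be a non-negative integer")

    def integrand(Lam):
        if Lam <= 0.0:
            return 0.0
        return float(
            np.exp(nb_logpmf(y, lam * Lam, alpha) + ge_logpdf(Lam, omega, v))
        )

    scan = [x / omega for x in (20.0, 50.0, 100.0, 400.0)]
    return _compound_quad(integrand, scan, "nbge_pmf_oracle")
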