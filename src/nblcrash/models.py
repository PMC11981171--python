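"""Declarative model specifications for the six crash-frequency hierarchies.

Families
--------
``NB``
    Fixed-parameter Negative Binomial: y ~ NB(lam, alpha), lam = exp(intercept + X beta).
``NB-GE``
    NB with a Generalized Exponential mixing variable: eta = lam * Lam,
    Lam ~ GE(omega, v).
``NB-L``
    NB with a Lindley mixing variable: eta = tau * lam, tau ~ Lindley(theta),
    augmented as tau ~ Gamma(1 + chi, theta), chi ~ Bernoulli(1/(1+theta)).
``RENB-L-alpha``
    NB-L with a per-observation overdispersion alpha_it; j_it = 1/(1+alpha_it)
    ~ Beta(a, b) with vague positive hyperpriors on a, b.
``RENB-L-intercept``
    NB-L with a per-observation intercept drawn N(c, d); vague hyperpriors on
    the hypermean c and hypervariance d.
``RPNB-L``
    NB-L with random regression coefficients beta_it = beta + w_it,
    w_it ~ N(0, sigma^2) independently per observation, for a declared subset
    of candidate covariates.

The NB kernel itself absorbs the multiplicative Gamma(1, alpha) noise of the
log link, so no separate epsilon latent is introduced: the kernel is the
likelihood primitive and the mixing layers act on its mean.

A :class:`ModelSpec` compiles to plain functions (linear predictor, NB mean,
log-likelihood, log mixing density, log prior) shared by the MCMC engine and
by the oracle-equivalence tests, so the sampled joint and the tested joint
are the same object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .distributions import ge_logpdf, nb_logpmf
from .panel import CrashPanel

__all__ = [
    "FAMILIES",
    "LINDLEY_FAMILIES",
    "PriorConfig",
    "ModelSpec",
    "LatentState",
    "ModelSpecError",
    "specify_model",
    "init_state",
    "linear_predictor",
    "nb_mean",
    "log_likelihood",
    "log_mixing",
    "log_prior",
    "log_joint",
]

FAMILIES = ("NB", "NB-GE", "NB-L", "RENB-L-alpha", "RENB-L-intercept", "RPNB-L")
#: Families carrying the Lindley tau/chi augmentation layer.
LINDLEY_FAMILIES = ("NB-L", "RENB-L-alpha", "RENB-L-intercept", "RPNB-L")


class ModelSpecError(ValueError):
    """Invalid model specification."""


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyper-parameters.  Gamma priors are (shape, rate) throughout.

    Defaults: regression coefficients N(0.01, sd 100) (variance 10000, read as
    a diffuse normal, not a BUGS precision); theta ~ Gamma(0.3, 0.5); GE omega
    and v ~ Gamma(0.01, 0.01); global alpha ~ Gamma(1, 0.01) — an Exponential
    with mean 100, finite at zero and effectively flat over the plausible
    range (a shape below 1 piles nearly all prior mass onto numerically tiny
    alpha and rewards degenerate Poisson exact-fit modes); the Beta(a,b)
    hyper-parameters of j = 1/(1+alpha_it) get Gamma(1, 0.1) hyperpriors; the
    random-intercept hypermean c ~ N(0, var 100) and hypervariance d ~
    Inv-Gamma(2, 1); random-coefficient sd sigma ~ half-normal(scale 2).
    """

    beta_loc: float = 0.01
    beta_var: float = 10000.0
    theta_shape: float = 0.3
    theta_rate: float = 0.5
    ge_shape: float = 0.01
    ge_rate: float = 0.01
    alpha_shape: float = 1.0
    alpha_rate: float = 0.01
    j_ab_shape: float = 1.0
    j_ab_rate: float = 0.1
    c_loc: float = 0.0
    c_var: float = 100.0
    d_shape: float = 2.0
    d_scale: float = 1.0
    sigma_scale: float = 2.0

    def __post_init__(self) -> None:
        for name in ("beta_var", "theta_shape", "theta_rate", "ge_shape", "ge_rate",
                     "alpha_shape", "alpha_rate", "j_ab_shape", "j_ab_rate", "c_var",
                     "d_shape", "d_scale", "sigma_scale"):
            if getattr(self, name) <= 0:
                raise ModelSpecError(f"prior hyper-parameter {name} must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """One of the six families plus covariate list, priors, random candidates."""

    family: str
    covariates: tuple
    priors: PriorConfig = field(default_factory=PriorConfig)
    random_candidates: tuple = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelSpecError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not self.covariates:
            raise ModelSpecError("covariate list must be non-empty")
        if len(set(self.covariates)) != len(self.covariates):
            raise ModelSpecError("duplicate covariates")
        if self.random_candidates and self.family != "RPNB-L":
            raise ModelSpecError("random_candidates are only valid for the RPNB-L family")
        unknown = set(self.random_candidates) - set(self.covariates)
        if unknown:
            raise ModelSpecError(f"random candidates not in covariate list: {sorted(unknown)}")

    @property
    def has_lindley(self) -> bool:
        return self.family in LINDLEY_FAMILIES

    def n_free_parameters(self) -> int:
        """Count of free global (non-latent, non-hyper-latent) parameters."""
        p = len(self.covariates)
        if self.family == "NB":
            return p + 2  # beta, intercept, alpha
        if self.family == "NB-GE":
            return p + 4  # + omega, v
        if self.family == "NB-L":
            return p + 3  # + theta
        if self.family == "RENB-L-alpha":
            return p + 4  # beta, intercept, theta, a, b
        if self.family == "RENB-L-intercept":
            return p + 4  # beta, alpha, theta, c, d
        # RPNB-L: beta means, sigmas, intercept, alpha, theta
        return p + len(self.random_candidates) + 3


def specify_model(family: str, covariates, priors: PriorConfig | None = None,
                  random_candidates=()) -> ModelSpec:
    """Build and validate a :class:`ModelSpec`."""
    return ModelSpec(
        family=family,
        covariates=tuple(covariates),
        priors=priors or PriorConfig(),
        random_candidates=tuple(random_candidates),
    )


@dataclass
class LatentState:
    """Concrete parameter + latent-variable values for one model.

    Array fields have length n = I*T.  Fields irrelevant to a family stay
    ``None``.  ``w`` and ``sigma`` are keyed by random-candidate name.
    """

    beta: np.ndarray
    intercept: float = 0.0
    alpha: float | None = None
    theta: float | None = None
    omega: float | None = None
    v: float | None = None
    tau: np.ndarray | None = None
    chi: np.ndarray | None = None
    Lam: np.ndarray | None = None
    j: np.ndarray | None = None
    a: float | None = None
    b: float | None = None
    intercept_re: np.ndarray | None = None
    c: float | None = None
    d: float | None = None
    w: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)

    def copy(self) -> "LatentState":
        out = LatentState(beta=self.beta.copy(), intercept=self.intercept,
                          alpha=self.alpha, theta=self.theta, omega=self.omega, v=self.v)
        for name in ("tau", "chi", "Lam", "j", "intercept_re"):
            val = getattr(self, name)
            setattr(out, name, None if val is None else val.copy())
        out.a, out.b, out.c, out.d = self.a, self.b, self.c, self.d
        out.w = {k: v.copy() for k, v in self.w.items()}
        out.sigma = dict(self.sigma)
        return out


def init_state(spec: ModelSpec, panel: CrashPanel) -> LatentState:
    """Deterministic initialization: beta at 0, positives at prior means, chi at 0."""
    n = panel.n
    pri = spec.priors
    state = LatentState(beta=np.zeros(len(spec.covariates)))
    if spec.family in ("NB", "NB-GE", "NB-L", "RENB-L-intercept", "RPNB-L"):
        state.alpha = 1.0  # unit overdispersion; the prior mean sits far into the tail
    if spec.has_lindley:
        state.theta = pri.theta_shape / pri.theta_rate
        state.tau = np.ones(n)
        state.chi = np.zeros(n, dtype=np.int8)
    if spec.family == "NB-GE":
        state.omega = 1.0
        state.v = 1.0
        state.Lam = np.ones(n)
    if spec.family == "RENB-L-alpha":
        state.alpha = None
        state.a = pri.j_ab_shape / pri.j_ab_rate
        state.b = pri.j_ab_shape / pri.j_ab_rate
        state.j = np.full(n, 0.5)
    if spec.family == "RENB-L-intercept":
        state.c = pri.c_loc
        state.d = pri.d_scale / (pri.d_shape - 1.0) if pri.d_shape > 1 else 1.0
        state.intercept_re = np.full(n, state.c)
    if spec.family == "RPNB-L":
        hn_mean = pri.sigma_scale * np.sqrt(2.0 / np.pi)
        for name in spec.random_candidates:
            state.w[name] = np.zeros(n)
            state.sigma[name] = hn_mean
    return state


# ---------------------------------------------------------------------------
# Log-density helpers (shape/rate Gamma; variance-parameterized normal)
# ---------------------------------------------------------------------------

def _normal_lp(x, loc, var):
    return -0.5 * np.log(2.0 * np.pi * var) - 0.5 * (np.asarray(x) - loc) ** 2 / var


def _gamma_lp(x, shape, rate):
    return shape * np.log(rate) - special.gammaln(shape) + (shape - 1.0) * np.log(x) - rate * np.asarray(x)


def _beta_lp(x, a, b):
    x = np.asarray(x)
    return (special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b)
            + (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x))


def _invgamma_lp(x, shape, scale):
    return shape * np.log(scale) - special.gammaln(shape) - (shape + 1.0) * np.log(x) - scale / np.asarray(x)


def _halfnormal_lp(x, scale):
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (np.asarray(x) / scale) ** 2


# ---------------------------------------------------------------------------
# Compiled model components
# ---------------------------------------------------------------------------

def linear_predictor(spec: ModelSpec, state: LatentState, X: np.ndarray) -> np.ndarray:
    """intercept + X beta (+ per-observation random deviations)."""
    xb = X @ state.beta
    if spec.family == "RENB-L-intercept":
        xb = xb + state.intercept_re
    else:
        xb = xb + state.intercept
    for name, w in state.w.items():
        k = spec.covariates.index(name)
        xb = xb + X[:, k] * w
    return xb


def nb_mean(spec: ModelSpec, state: LatentState, X: np.ndarray) -> np.ndarray:
    """The NB kernel mean eta_it: lam for NB, tau*lam or Lam*lam for mixtures."""
    lam = np.exp(linear_predictor(spec, state, X))
    if spec.has_lindley:
        return state.tau * lam
    if spec.family == "NB-GE":
        return state.Lam * lam
    return lam


def _obs_alpha(spec: ModelSpec, state: LatentState):
    if spec.family == "RENB-L-alpha":
        return (1.0 - state.j) / state.j
    return state.alpha


def log_likelihood(spec: ModelSpec, state: LatentState, panel: CrashPanel,
                   X: np.ndarray | None = None) -> float:
    """Sum over cells of the NB kernel log pmf at the current state."""
    if X is None:
        X = panel.design_matrix(list(spec.covariates))
    if X.shape[0] != panel.n:
        raise ModelSpecError("state/design dimensions do not match the panel")
    eta = nb_mean(spec, state, X)
    return float(np.sum(nb_logpmf(panel.y, eta, _obs_alpha(spec, state))))


def log_mixing(spec: ModelSpec, state: LatentState) -> float:
    """Log density of every latent layer given its (hyper-)parameters.

    The Lindley layer enters through its Bernoulli-Gamma augmentation:
    log Gamma(tau; 1 + chi, theta) + log Bernoulli(chi; 1/(1+theta)).
    """
    total = 0.0
    if spec.has_lindley:
        th, tau, chi = state.theta, state.tau, state.chi
        total += float(np.sum(_gamma_lp(tau, 1.0 + chi, th)))
        p1 = 1.0 / (1.0 + th)
        total += float(np.sum(np.where(chi == 1, np.log(p1), np.log1p(-p1))))
    if spec.family == "NB-GE":
        total += float(np.sum(ge_logpdf(state.Lam, state.omega, state.v)))
    if spec.family == "RENB-L-alpha":
        total += float(np.sum(_beta_lp(state.j, state.a, state.b)))
    if spec.family == "RENB-L-intercept":
        total += float(np.sum(_normal_lp(state.intercept_re, state.c, state.d)))
    for name in spec.random_candidates:
        sig = state.sigma[name]
        total += float(np.sum(_normal_lp(state.w[name], 0.0, sig**2)))
    return total


def log_prior(spec: ModelSpec, state: LatentState) -> float:
    """Log prior of the global parameters."""
    pri = spec.priors
    total = float(np.sum(_normal_lp(state.beta, pri.beta_loc, pri.beta_var)))
    if spec.family != "RENB-L-intercept":
        total += float(_normal_lp(state.intercept, pri.beta_loc, pri.beta_var))
    if state.alpha is not None:
        total += float(_gamma_lp(state.alpha, pri.alpha_shape, pri.alpha_rate))
    if spec.has_lindley:
        total += float(_gamma_lp(state.theta, pri.theta_shape, pri.theta_rate))
    if spec.family == "NB-GE":
        total += float(_gamma_lp(state.omega, pri.ge_shape, pri.ge_rate))
        total += float(_gamma_lp(state.v, pri.ge_shape, pri.ge_rate))
    if spec.family == "RENB-L-alpha":
        total += float(_gamma_lp(state.a, pri.j_ab_shape, pri.j_ab_rate))
        total += float(_gamma_lp(state.b, pri.j_ab_shape, pri.j_ab_rate))
    if spec.family == "RENB-L-intercept":
        total += float(_normal_lp(state.c, pri.c_loc, pri.c_var))
        total += float(_invgamma_lp(state.d, pri.d_shape, pri.d_scale))
    for name in spec.random_candidates:
        total += float(_halfnormal_lp(state.sigma[name], pri.sigma_scale))
    return total


def log_joint(spec: ModelSpec, state: LatentState, panel: CrashPanel,
              X: np.ndarray | None = None) -> float:
    """log likelihood + log mixing + log prior at the given state."""
    return (log_likelihood(spec, state, panel, X)
            + log_mixing(spec, state)
            + log_prior(spec, state))
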