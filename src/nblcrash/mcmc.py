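"""Metropolis-within-Gibbs estimation for the compiled crash-frequency models.

The sampler exploits the conditional independence of the per-observation
latent variables (tau/chi for the Lindley layer, Lam for the GE layer, and
the random-effect/random-parameter deviations): each latent vector is updated
in one vectorized Metropolis step with element-wise accept/reject.  The
Bernoulli mixture indicator chi has an exact full conditional,
``P(chi=1 | tau) = tau / (1 + tau)``, and the random-intercept
hyper-parameters (c, d) are conjugate (normal / inverse-gamma) and Gibbs
sampled.  All remaining blocks use adaptive random-walk proposals on
unconstrained scales (log for positive parameters, logit for j in (0,1)),
with per-block step sizes tuned toward a 0.25-0.45 acceptance rate during
burn-in and frozen afterwards to preserve detailed balance.

For Metropolis ratios that hold the overdispersion fixed, the
``Gamma(1/alpha + y)`` terms of the NB kernel cancel; the engine therefore
caches only the mean-dependent part of the log pmf and restores the constant
terms when the deviance is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import models as M
from .panel import CrashPanel

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "FitResult",
    "McmcError",
    "InitializationError",
    "DivergenceError",
    "fit",
    "gelman_rubin",
    "summarize",
]


class McmcError(RuntimeError):
    """Sampler-level failure."""


class InitializationError(McmcError):
    """The log-joint is non-finite at the initial state."""


class DivergenceError(McmcError):
    """The chain state became non-finite."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    The defaults run 4 chains of 25000 iterations with a 10000-iteration
    burn-in, which keeps split-R-hat available; a single long chain (e.g.
    100000 iterations, 70000 burn-in) can be requested instead but then no
    convergence statistic is computed.  ``likelihood_scale`` exists for
    sampler-correctness checks (0.0 samples the prior/mixing layers only).
    """

    chains: int = 4
    iterations: int = 25000
    burn_in: int = 10000
    thin: int = 5
    seed: int = 0
    adapt_window: int = 50
    likelihood_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise McmcError("chains must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise McmcError("require 0 <= burn_in < iterations")
        if self.thin < 1:
            raise McmcError("thin must be >= 1")
        if self.likelihood_scale not in (0.0, 1.0):
            raise McmcError("likelihood_scale must be 0.0 or 1.0")


@dataclass
class PosteriorDraws:
    """Post burn-in, thinned draws: one (chains, n_draws) array per parameter."""

    params: dict

    def __post_init__(self) -> None:
        lengths = {v.shape for v in self.params.values()}
        if len(lengths) > 1:
            raise McmcError(f"unequal draw shapes across parameters: {lengths}")

    @property
    def names(self) -> list:
        return list(self.params)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat vector."""
        return self.params[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain label column plus one column per parameter."""
        n_chains, n_draws = next(iter(self.params.values())).shape
        out = {"chain": np.repeat(np.arange(n_chains), n_draws)}
        for name, arr in self.params.items():
            out[name] = arr.reshape(-1)
        return pd.DataFrame(out)


@dataclass
class FitResult:
    """Posterior draws, summaries, convergence and fit indices for one model."""

    spec: M.ModelSpec
    config: McmcConfig
    draws: PosteriorDraws
    summaries: pd.DataFrame
    rhat: dict | None
    dbar: float
    pd_eff: float
    dic: float
    fitted: np.ndarray
    deviance_at_mean: float
    acceptance: dict
    latent_means: dict

    @property
    def pd(self) -> float:  # effective number of parameters, P_D
        return self.pd_eff


# ---------------------------------------------------------------------------
# Convergence diagnostics and summaries
# ---------------------------------------------------------------------------

def _rhat(chains_2d: np.ndarray) -> float:
    """Potential scale reduction factor of a (chains, draws) array.

    R-hat = sqrt((W + B/n) / W) with W the mean within-chain variance and B
    the between-chain variance of the chain means.  Chains that are exact
    copies give exactly 1 (B = 0); well-separated chains give values far
    above the 1.05 convergence threshold.
    """
    m, n = chains_2d.shape
    if n < 2:
        return float("nan")
    means = chains_2d.mean(axis=1)
    w = chains_2d.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0
    return float(np.sqrt((w + b / n) / w))


def gelman_rubin(draws: PosteriorDraws) -> dict:
    """Gelman-Rubin R-hat per parameter; requires at least 2 chains.

    Convergence is conventionally declared at R-hat < 1.05.
    """
    if draws.n_chains < 2:
        raise McmcError("Gelman-Rubin requires >= 2 chains; run with chains >= 2")
    return {name: _rhat(arr) for name, arr in draws.params.items()}


def summarize(draws: PosteriorDraws, rhat: dict | None = None) -> pd.DataFrame:
    """Mean, sd, equal-tailed 95% interval and a significance flag per parameter.

    A parameter is flagged significant when its 95% credible interval
    excludes zero.
    """
    if not draws.params:
        raise McmcError("no draws to summarize")
    rows = []
    for name in draws.names:
        x = draws.stacked(name)
        lo, hi = np.quantile(x, [0.025, 0.975])
        row = {
            "parameter": name,
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "q2.5": float(lo),
            "q97.5": float(hi),
            "significant": bool(lo > 0.0 or hi < 0.0),
        }
        if rhat is not None:
            row["rhat"] = rhat.get(name, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Chain internals
# ---------------------------------------------------------------------------

#: Positive scale-type parameters are restricted to exp(+/- _LOG_BOX): the
#: mixing-scale ridge is likelihood-invariant and only weakly tethered by the
#: vague priors, so untruncated random walks can reach numerically
#: unrepresentable states.  Rejecting proposals outside the box is an exact
#: truncation of the priors and leaves all identified quantities untouched.
_LOG_BOX = 12.0


def _eta_ll(y: np.ndarray, eta: np.ndarray, r) -> np.ndarray:
    """Mean-dependent part of the NB log pmf (Gamma terms omitted)."""
    ld = np.log(r + eta)
    return r * (np.log(r) - ld) + y * (np.log(eta) - ld)


class _AdaptiveScales:
    """Per-block random-walk scales with windowed Robbins-Monro adaptation."""

    def __init__(self, window: int):
        self.window = window
        self.scales: dict = {}
        self.acc: dict = {}
        self.tries: dict = {}
        self.total_acc: dict = {}
        self.total_tries: dict = {}
        self.frozen = False

    def get(self, name: str, default: float = 0.3) -> float:
        return self.scales.setdefault(name, default)

    def record(self, name: str, accepted: float, tries: float = 1.0) -> None:
        self.acc[name] = self.acc.get(name, 0.0) + accepted
        self.tries[name] = self.tries.get(name, 0.0) + tries
        self.total_acc[name] = self.total_acc.get(name, 0.0) + accepted
        self.total_tries[name] = self.total_tries.get(name, 0.0) + tries

    def maybe_adapt(self, target: float = 0.35) -> None:
        if self.frozen:
            self.acc.clear()
            self.tries.clear()
            return
        for name, tries in self.tries.items():
            if tries >= self.window:
                rate = self.acc[name] / tries
                factor = math.exp(max(-1.0, min(1.0, rate - target)))
                self.scales[name] = min(1e3, max(1e-6, self.scales[name] * factor))
                self.acc[name] = 0.0
                self.tries[name] = 0.0

    def rates(self) -> dict:
        return {k: self.total_acc[k] / max(self.total_tries[k], 1.0)
                for k in self.total_tries}


class _ChainState:
    """Mutable caches for one chain of one compiled model."""

    def __init__(self, spec: M.ModelSpec, panel: CrashPanel, X: np.ndarray,
                 rng: np.random.Generator, ls: float, window: int):
        self.spec = spec
        self.pri = spec.priors
        self.rng = rng
        self.ls = ls  # likelihood scale (1.0, or 0.0 for prior-only checks)
        self.X = X
        self.y = panel.y.astype(float)
        self.n = panel.n
        self.state = M.init_state(spec, panel)
        self.gammaln_y1 = special.gammaln(self.y + 1.0)
        self.scales = _AdaptiveScales(window)
        self.has_lindley = spec.has_lindley
        self.has_ge = spec.family == "NB-GE"
        self.has_j = spec.family == "RENB-L-alpha"
        self.has_ere = spec.family == "RENB-L-intercept"
        self.rp_names = list(spec.random_candidates)
        self.refresh()

    # -- cache management ---------------------------------------------------
    def refresh(self) -> None:
        """Recompute lam, mix, r and the cached likelihood part from scratch."""
        s = self.state
        self.lam = np.exp(M.linear_predictor(self.spec, s, self.X))
        if self.has_lindley:
            self.mix = s.tau
        elif self.has_ge:
            self.mix = s.Lam
        else:
            self.mix = np.ones(self.n)
        self.r = s.j / (1.0 - s.j) if self.has_j else 1.0 / s.alpha
        self.ell = _eta_ll(self.y, self.mix * self.lam, self.r)
        if self.ls != 0.0 and not np.all(np.isfinite(self.ell)):
            raise DivergenceError("non-finite likelihood cache; chain diverged")

    def deviance(self) -> float:
        """-2 x conditional NB log-likelihood at the current state."""
        const = special.gammaln(self.r + self.y) - special.gammaln(self.r) - self.gammaln_y1
        return float(-2.0 * np.sum(const + self.ell))

    # -- vectorized latent updates -----------------------------------------
    def update_tau(self) -> None:
        s = self.state
        scale = self.scales.get("tau", 0.5)
        ltau = np.log(s.tau)
        ltau_p = ltau + scale * self.rng.standard_normal(self.n)
        tau_p = np.exp(ltau_p)
        ell_p = _eta_ll(self.y, tau_p * self.lam, self.r)
        dl = ltau_p - ltau
        logr = (self.ls * (ell_p - self.ell)
                + s.chi * dl - s.theta * (tau_p - s.tau) + dl)
        acc = np.log(self.rng.random(self.n)) < logr
        s.tau[acc] = tau_p[acc]
        self.ell[acc] = ell_p[acc]
        self.scales.record("tau", float(acc.mean()))

    def update_chi(self) -> None:
        s = self.state
        p1 = s.tau / (1.0 + s.tau)
        s.chi = (self.rng.random(self.n) < p1).astype(np.int8)

    def update_theta(self) -> None:
        # Augmented Lindley layer: chi terms cancel, leaving
        # 2N log(theta) - N log(1+theta) - theta * sum(tau) plus the prior.
        s = self.state
        st = float(np.sum(s.tau))

        def logp(th):
            return (2.0 * self.n * math.log(th) - self.n * math.log1p(th) - th * st
                    + (self.pri.theta_shape - 1.0) * math.log(th) - self.pri.theta_rate * th)

        self._scalar_mh_log("theta", s.theta, logp, lambda v: setattr(s, "theta", v))

    def update_Lam(self) -> None:
        s = self.state
        scale = self.scales.get("Lam", 0.5)
        lL = np.log(s.Lam)
        lL_p = lL + scale * self.rng.standard_normal(self.n)
        Lam_p = np.exp(lL_p)
        ell_p = _eta_ll(self.y, Lam_p * self.lam, self.r)
        logr = self.ls * (ell_p - self.ell) + self._ge_core(Lam_p) - self._ge_core(s.Lam) + (lL_p - lL)
        acc = np.log(self.rng.random(self.n)) < logr
        s.Lam[acc] = Lam_p[acc]
        self.ell[acc] = ell_p[acc]
        self.scales.record("Lam", float(acc.mean()))

    def _ge_core(self, Lam):
        s = self.state
        if s.v == 1.0:
            return -s.omega * Lam
        return (s.v - 1.0) * np.log(-np.expm1(-s.omega * Lam)) - s.omega * Lam

    def update_ge_params(self) -> None:
        s = self.state

        def logp_omega(om):
            core = (s.v - 1.0) * np.sum(np.log(-np.expm1(-om * s.Lam))) if s.v != 1.0 else 0.0
            return (self.n * math.log(om) + core - om * float(np.sum(s.Lam))
                    + (self.pri.ge_shape - 1.0) * math.log(om) - self.pri.ge_rate * om)

        self._scalar_mh_log("omega", s.omega, logp_omega, lambda v: setattr(s, "omega", v))

        lse = float(np.sum(np.log(-np.expm1(-s.omega * s.Lam))))

        def logp_v(v):
            return (self.n * math.log(v) + (v - 1.0) * lse
                    + (self.pri.ge_shape - 1.0) * math.log(v) - self.pri.ge_rate * v)

        self._scalar_mh_log("v", s.v, logp_v, lambda v: setattr(s, "v", v))

    def update_j(self) -> None:
        s = self.state
        scale = self.scales.get("j", 0.5)
        logit = np.log(s.j) - np.log1p(-s.j)
        logit_p = logit + scale * self.rng.standard_normal(self.n)
        j_p = 1.0 / (1.0 + np.exp(-logit_p))
        j_p = np.clip(j_p, 1e-12, 1.0 - 1e-12)
        r_p = j_p / (1.0 - j_p)
        eta = self.mix * self.lam
        # r changes per observation: the Gamma terms do not cancel here.
        full = (special.gammaln(self.r + self.y) - special.gammaln(self.r) + self.ell)
        ell_p = _eta_ll(self.y, eta, r_p)
        full_p = (special.gammaln(r_p + self.y) - special.gammaln(r_p) + ell_p)
        lj, lj_p = np.log(s.j), np.log(j_p)
        l1j, l1j_p = np.log1p(-s.j), np.log1p(-j_p)
        logr = (self.ls * (full_p - full)
                + (s.a - 1.0) * (lj_p - lj) + (s.b - 1.0) * (l1j_p - l1j)
                + (lj_p + l1j_p) - (lj + l1j))
        acc = np.log(self.rng.random(self.n)) < logr
        s.j[acc] = j_p[acc]
        self.r = s.j / (1.0 - s.j)
        self.ell[acc] = ell_p[acc]
        self.scales.record("j", float(acc.mean()))

    def update_ab(self) -> None:
        s = self.state
        slj = float(np.sum(np.log(s.j)))
        sl1j = float(np.sum(np.log1p(-s.j)))

        def make_logp(other_is_b: bool):
            def logp(x):
                a, b = (s.a, x) if other_is_b else (x, s.b)
                return (self.n * (special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b))
                        + (a - 1.0) * slj + (b - 1.0) * sl1j
                        + (self.pri.j_ab_shape - 1.0) * math.log(x) - self.pri.j_ab_rate * x)
            return logp

        self._scalar_mh_log("a", s.a, make_logp(False), lambda v: setattr(s, "a", v))
        self._scalar_mh_log("b", s.b, make_logp(True), lambda v: setattr(s, "b", v))

    def update_intercept_re(self) -> None:
        s = self.state
        scale = self.scales.get("e", 0.3)
        delta = scale * self.rng.standard_normal(self.n)
        e_p = s.intercept_re + delta
        lam_p = self.lam * np.exp(delta)
        ell_p = _eta_ll(self.y, self.mix * lam_p, self.r)
        logr = (self.ls * (ell_p - self.ell)
                - ((e_p - s.c) ** 2 - (s.intercept_re - s.c) ** 2) / (2.0 * s.d))
        acc = np.log(self.rng.random(self.n)) < logr
        s.intercept_re[acc] = e_p[acc]
        self.lam[acc] = lam_p[acc]
        self.ell[acc] = ell_p[acc]
        self.scales.record("e", float(acc.mean()))

    def update_cd(self) -> None:
        # Conjugate Gibbs draws for the random-intercept hyper-parameters.
        s = self.state
        pri = self.pri
        prec = self.n / s.d + 1.0 / pri.c_var
        mean = (float(np.sum(s.intercept_re)) / s.d + pri.c_loc / pri.c_var) / prec
        s.c = float(self.rng.normal(mean, math.sqrt(1.0 / prec)))
        sse = float(np.sum((s.intercept_re - s.c) ** 2))
        shape = pri.d_shape + 0.5 * self.n
        scale_ig = pri.d_scale + 0.5 * sse
        s.d = float(scale_ig / self.rng.gamma(shape))

    def update_w(self, name: str) -> None:
        s = self.state
        k = self.spec.covariates.index(name)
        xk = self.X[:, k]
        scale = self.scales.get(f"w:{name}", 0.3)
        delta = scale * self.rng.standard_normal(self.n)
        w_p = s.w[name] + delta
        lam_p = self.lam * np.exp(xk * delta)
        ell_p = _eta_ll(self.y, self.mix * lam_p, self.r)
        sig2 = s.sigma[name] ** 2
        logr = (self.ls * (ell_p - self.ell)
                - (w_p ** 2 - s.w[name] ** 2) / (2.0 * sig2))
        acc = np.log(self.rng.random(self.n)) < logr
        s.w[name][acc] = w_p[acc]
        self.lam[acc] = lam_p[acc]
        self.ell[acc] = ell_p[acc]
        self.scales.record(f"w:{name}", float(acc.mean()))

    def update_sigma(self, name: str) -> None:
        s = self.state
        sw2 = float(np.sum(s.w[name] ** 2))

        def logp(sig):
            return (-self.n * math.log(sig) - sw2 / (2.0 * sig**2)
                    - 0.5 * (sig / self.pri.sigma_scale) ** 2)

        self._scalar_mh_log(f"sigma:{name}", s.sigma[name], logp,
                            lambda v: s.sigma.__setitem__(name, v))

    # -- regression-block updates -------------------------------------------
    def update_beta(self) -> None:
        s = self.state
        pri = self.pri
        for k, cov in enumerate(self.spec.covariates):
            name = f"beta:{cov}"
            scale = self.scales.get(name, 0.1)
            delta = scale * self.rng.standard_normal()
            lam_p = self.lam * np.exp(self.X[:, k] * delta)
            ell_p = _eta_ll(self.y, self.mix * lam_p, self.r)
            b_p = s.beta[k] + delta
            logr = (self.ls * float(np.sum(ell_p - self.ell))
                    - ((b_p - pri.beta_loc) ** 2 - (s.beta[k] - pri.beta_loc) ** 2)
                    / (2.0 * pri.beta_var))
            if math.log(self.rng.random()) < logr:
                s.beta[k] = b_p
                self.lam = lam_p
                self.ell = ell_p
                self.scales.record(name, 1.0)
            else:
                self.scales.record(name, 0.0)
        if not self.has_ere:
            name = "intercept"
            scale = self.scales.get(name, 0.1)
            delta = scale * self.rng.standard_normal()
            lam_p = self.lam * float(np.exp(delta))
            ell_p = _eta_ll(self.y, self.mix * lam_p, self.r)
            i_p = s.intercept + delta
            logr = (self.ls * float(np.sum(ell_p - self.ell))
                    - ((i_p - pri.beta_loc) ** 2 - (s.intercept - pri.beta_loc) ** 2)
                    / (2.0 * pri.beta_var))
            if math.log(self.rng.random()) < logr:
                s.intercept = i_p
                self.lam = lam_p
                self.ell = ell_p
                self.scales.record(name, 1.0)
            else:
                self.scales.record(name, 0.0)

    def update_beta_centered(self) -> None:
        """Interweaved (centered) coefficient updates for mixture families.

        Proposes beta_k -> beta_k + delta while rescaling the mixing vector
        by exp(-delta * x_k) cell-wise, which keeps every NB mean eta fixed.
        The move is judged by the mixing density alone, giving a first-order
        restoring force along the exact-fit manifold where the non-centered
        update is second-order flat (ancillarity-sufficiency interweaving).
        """
        s = self.state
        pri = self.pri
        mix = s.tau if self.has_lindley else s.Lam
        for k, cov in enumerate(self.spec.covariates):
            name = f"betaC:{cov}"
            scale = self.scales.get(name, 0.1)
            delta = scale * self.rng.standard_normal()
            xk = self.X[:, k]
            shift = -delta * xk
            mix_p = mix * np.exp(shift)
            if self.has_lindley:
                core = (float(np.sum(s.chi * shift))
                        - s.theta * float(np.sum(mix_p - mix)))
            else:
                core = float(np.sum(self._ge_core(mix_p) - self._ge_core(mix)))
            b_p = s.beta[k] + delta
            logr = (core + float(np.sum(shift))  # Jacobian of the cell-wise rescale
                    - ((b_p - pri.beta_loc) ** 2 - (s.beta[k] - pri.beta_loc) ** 2)
                    / (2.0 * pri.beta_var))
            if math.log(self.rng.random()) < logr:
                s.beta[k] = b_p
                mix[:] = mix_p
                self.lam = self.lam * np.exp(delta * xk)  # eta = mix*lam unchanged
                self.scales.record(name, 1.0)
            else:
                self.scales.record(name, 0.0)

    def update_alpha(self) -> None:
        s = self.state
        if s.alpha is None:
            return
        pri = self.pri
        scale = self.scales.get("alpha", 0.2)
        la_p = math.log(s.alpha) + scale * self.rng.standard_normal()
        a_p = math.exp(la_p)
        r_p = 1.0 / a_p
        eta = self.mix * self.lam
        ell_p = _eta_ll(self.y, eta, r_p)
        full = float(np.sum(special.gammaln(self.r + self.y) + self.ell)) \
            - self.n * float(special.gammaln(self.r))
        full_p = float(np.sum(special.gammaln(r_p + self.y) + ell_p)) \
            - self.n * float(special.gammaln(r_p))
        logr = (self.ls * (full_p - full)
                + (pri.alpha_shape - 1.0) * (math.log(a_p) - math.log(s.alpha))
                - pri.alpha_rate * (a_p - s.alpha)
                + (la_p - math.log(s.alpha)))
        if math.log(self.rng.random()) < logr:
            s.alpha = a_p
            self.r = r_p
            self.ell = ell_p
            self.scales.record("alpha", 1.0)
        else:
            self.scales.record("alpha", 0.0)

    # -- ridge moves ----------------------------------------------------------
    # The NB mean eta = mix * exp(intercept + ...) is invariant under
    # (mix, intercept) -> (mix * s, intercept - log s); the posterior is
    # therefore strongly ridged along that direction and element-wise updates
    # alone mix slowly.  The moves below propose along the ridge with the
    # exact Jacobian of the deterministic transform, leaving the likelihood
    # untouched.

    def _shift_intercept_logdiff(self, shift: float) -> float:
        """Log prior/mixing change from intercept -> intercept + shift."""
        s = self.state
        pri = self.pri
        if self.has_ere:
            # shift the whole random-intercept field and its hypermean:
            # N(e - c, d) terms are invariant, only the c prior moves.
            c_p = s.c + shift
            return float(M._normal_lp(c_p, pri.c_loc, pri.c_var)
                         - M._normal_lp(s.c, pri.c_loc, pri.c_var))
        i_p = s.intercept + shift
        return float(M._normal_lp(i_p, pri.beta_loc, pri.beta_var)
                     - M._normal_lp(s.intercept, pri.beta_loc, pri.beta_var))

    def _apply_intercept_shift(self, shift: float) -> None:
        s = self.state
        if self.has_ere:
            s.intercept_re += shift
            s.c += shift
        else:
            s.intercept += shift

    def move_rescale_mix(self) -> None:
        """Rescale the mixing vector by s and shift the intercept by -log s."""
        s = self.state
        scale = self.scales.get("rescale", 0.2)
        ls_ = scale * self.rng.standard_normal()
        fac = float(np.exp(ls_))
        if self.has_lindley:
            # Gamma(tau*s; 1+chi, theta) terms + Jacobian n*log s
            logr = (float(np.sum(s.chi)) * ls_
                    - s.theta * (fac - 1.0) * float(np.sum(s.tau))
                    + self.n * ls_)
        else:  # GE layer
            logr = (float(np.sum(self._ge_core(s.Lam * fac) - self._ge_core(s.Lam)))
                    + self.n * ls_)
        logr += self._shift_intercept_logdiff(-ls_)
        if math.log(self.rng.random()) < logr:
            if self.has_lindley:
                s.tau *= fac
            else:
                s.Lam *= fac
            self._apply_intercept_shift(-ls_)
            self.lam = self.lam * float(np.exp(-ls_))
            self.scales.record("rescale", 1.0)
        else:
            self.scales.record("rescale", 0.0)

    def move_theta_recenter(self) -> None:
        """Update theta while rescaling tau to keep its mean (and eta) fixed."""
        from .distributions import lindley_mean

        s = self.state
        scale = self.scales.get("theta_rc", 0.3)
        lth = math.log(s.theta)
        lth_p = lth + scale * self.rng.standard_normal()
        if abs(lth_p) > _LOG_BOX:  # proper truncation of the scale ridge
            self.scales.record("theta_rc", 0.0)
            return
        th_p = math.exp(lth_p)
        m = lindley_mean(th_p) / lindley_mean(s.theta)
        lm = math.log(m)
        stau = float(np.sum(s.tau))
        schi = float(np.sum(s.chi))
        logr = (2.0 * self.n * (lth_p - lth)
                - self.n * (math.log1p(th_p) - math.log1p(s.theta))
                - (th_p * m - s.theta) * stau
                + schi * lm
                + (self.pri.theta_shape - 1.0) * (lth_p - lth)
                - self.pri.theta_rate * (th_p - s.theta)
                + (lth_p - lth)      # Jacobian of the log-scale theta walk
                + self.n * lm        # Jacobian of the tau rescaling
                + self._shift_intercept_logdiff(-lm))
        if math.log(self.rng.random()) < logr:
            s.theta = th_p
            s.tau *= m
            self._apply_intercept_shift(-lm)
            self.lam = self.lam * float(np.exp(-lm))
            self.scales.record("theta_rc", 1.0)
        else:
            self.scales.record("theta_rc", 0.0)

    def move_omega_recenter(self) -> None:
        """Update omega while rescaling Lam by omega/omega'; eta is invariant.

        GE is a scale family in omega, so the GE density terms cancel exactly
        against the Jacobian of the Lam rescaling, leaving only the omega
        prior, the proposal Jacobian, and the intercept-shift prior change.
        """
        s = self.state
        scale = self.scales.get("omega_rc", 0.4)
        lom = math.log(s.omega)
        lom_p = lom + scale * self.rng.standard_normal()
        if abs(lom_p) > _LOG_BOX:
            self.scales.record("omega_rc", 0.0)
            return
        om_p = math.exp(lom_p)
        m = s.omega / om_p
        lm = math.log(m)
        logr = ((self.pri.ge_shape - 1.0) * (lom_p - lom)
                - self.pri.ge_rate * (om_p - s.omega)
                + (lom_p - lom)
                + self._shift_intercept_logdiff(-lm))
        if math.log(self.rng.random()) < logr:
            s.omega = om_p
            s.Lam *= m
            self._apply_intercept_shift(-lm)
            self.lam = self.lam * float(np.exp(-lm))
            self.scales.record("omega_rc", 1.0)
        else:
            self.scales.record("omega_rc", 0.0)

    # -- scalar MH helper -----------------------------------------------------
    def _scalar_mh_log(self, name: str, current: float, logp, setter) -> None:
        """Random-walk MH on log scale for a positive scalar; logp excludes Jacobian."""
        scale = self.scales.get(name, 0.2)
        lx = math.log(current)
        lx_p = lx + scale * self.rng.standard_normal()
        if abs(lx_p) > _LOG_BOX:
            self.scales.record(name, 0.0)
            return
        x_p = math.exp(lx_p)
        try:
            logr = logp(x_p) - logp(current) + (lx_p - lx)
        except (ValueError, OverflowError):
            logr = -math.inf
        if math.log(self.rng.random()) < logr:
            setter(x_p)
            self.scales.record(name, 1.0)
        else:
            self.scales.record(name, 0.0)

    # -- one full sweep -------------------------------------------------------
    def sweep(self) -> None:
        if self.has_lindley:
            self.update_tau()
            self.update_chi()
            self.update_theta()
            self.move_rescale_mix()
            self.move_theta_recenter()
        if self.has_ge:
            self.update_Lam()
            self.update_ge_params()
            self.move_rescale_mix()
            self.move_omega_recenter()
        if self.has_j:
            self.update_j()
            self.update_ab()
        if self.has_ere:
            self.update_intercept_re()
            self.update_cd()
        for name in self.rp_names:
            self.update_w(name)
            self.update_sigma(name)
        self.update_beta()
        if self.has_lindley or self.has_ge:
            self.update_beta_centered()
        self.update_alpha()


def _scalar_param_values(spec: M.ModelSpec, state: M.LatentState) -> dict:
    out = {}
    for k, cov in enumerate(spec.covariates):
        out[f"beta[{cov}]"] = state.beta[k]
    if spec.family != "RENB-L-intercept":
        out["intercept"] = state.intercept
    if state.alpha is not None:
        out["alpha"] = state.alpha
    if spec.has_lindley:
        out["theta"] = state.theta
    if spec.family == "NB-GE":
        out["omega"], out["v"] = state.omega, state.v
    if spec.family == "RENB-L-alpha":
        out["a"], out["b"] = state.a, state.b
    if spec.family == "RENB-L-intercept":
        out["c"], out["d"] = state.c, state.d
    for name in spec.random_candidates:
        out[f"sigma[{name}]"] = state.sigma[name]
    return out


def _run_chain(spec: M.ModelSpec, panel: CrashPanel, X: np.ndarray,
               cfg: McmcConfig, seed_seq: np.random.SeedSequence) -> dict:
    rng = np.random.default_rng(seed_seq)
    cs = _ChainState(spec, panel, X, rng, cfg.likelihood_scale, cfg.adapt_window)
    n = panel.n
    traces: dict = {k: [] for k in _scalar_param_values(spec, cs.state)}
    acc_eta = np.zeros(n)
    acc_alpha = np.zeros(n)
    latent_sums = {name: np.zeros(n) for name in ("tau", "chi", "Lam", "j", "intercept_re")}
    w_sums = {name: np.zeros(n) for name in spec.random_candidates}
    dev_sum = 0.0
    kept = 0
    for it in range(cfg.iterations):
        # overflow/invalid in rejected proposals is expected; guarded by the
        # periodic finite-state checks below
        with np.errstate(over="ignore", divide="ignore", invalid="ignore", under="ignore"):
            cs.sweep()
        if it < cfg.burn_in:
            if (it + 1) % cfg.adapt_window == 0:
                cs.scales.maybe_adapt()
                if cs.ls != 0.0 and not np.all(np.isfinite(cs.ell)):
                    raise DivergenceError(
                        f"non-finite state at iteration {it}; acceptance so far: {cs.scales.rates()}"
                    )
            if it + 1 == cfg.burn_in:
                cs.scales.frozen = True
                cs.refresh()  # clear any incremental drift before sampling
        elif (it - cfg.burn_in) % cfg.thin == 0:
            for name, val in _scalar_param_values(spec, cs.state).items():
                traces[name].append(val)
            acc_eta += cs.mix * cs.lam
            acc_alpha += (1.0 - cs.state.j) / cs.state.j if cs.has_j else cs.state.alpha
            for name in latent_sums:
                val = getattr(cs.state, name)
                if val is not None:
                    latent_sums[name] += val
            for name in spec.random_candidates:
                w_sums[name] += cs.state.w[name]
            dev_sum += cs.deviance()
            kept += 1
    return {
        "traces": {k: np.asarray(v) for k, v in traces.items()},
        "eta_sum": acc_eta,
        "alpha_sum": acc_alpha,
        "latent_sums": latent_sums,
        "w_sums": w_sums,
        "dev_sum": dev_sum,
        "kept": kept,
        "acceptance": cs.scales.rates(),
    }


def _check_init(spec: M.ModelSpec, panel: CrashPanel, X: np.ndarray) -> None:
    state = M.init_state(spec, panel)
    parts = {
        "log_likelihood": M.log_likelihood(spec, state, panel, X),
        "log_mixing": M.log_mixing(spec, state),
        "log_prior": M.log_prior(spec, state),
    }
    bad = [k for k, v in parts.items() if not np.isfinite(v)]
    if bad:
        raise InitializationError(f"non-finite log-joint at initialization: {bad} = "
                                  f"{[parts[k] for k in bad]}")


def fit(spec: M.ModelSpec, panel: CrashPanel, cfg: McmcConfig | None = None) -> FitResult:
    """Sample the posterior of ``spec`` on ``panel`` and assemble fit indices.

    Returns a :class:`FitResult` with draws, summaries (mean, sd, 95% BCI,
    significance flag, split-R-hat when >= 2 chains), the DIC decomposition
    (Dbar, P_D), and the fitted NB means ybar averaged over posterior draws.
    Reproducible: identical spec/panel/config give identical draws.
    """
    cfg = cfg or McmcConfig()
    missing = [c for c in spec.covariates
               if c not in panel.schema.model_names and c not in panel.schema.names]
    if missing:
        raise McmcError(f"panel schema does not cover covariates: {missing}")
    X = panel.design_matrix(list(spec.covariates))
    _check_init(spec, panel, X)
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    results = [_run_chain(spec, panel, X, cfg, s) for s in seqs]

    names = list(results[0]["traces"])
    params = {name: np.stack([r["traces"][name] for r in results]) for name in names}
    draws = PosteriorDraws(params)
    rhat = gelman_rubin(draws) if cfg.chains >= 2 else None
    summaries = summarize(draws, rhat)

    kept_total = sum(r["kept"] for r in results)
    fitted = sum(r["eta_sum"] for r in results) / kept_total
    dbar = sum(r["dev_sum"] for r in results) / kept_total

    # Plug-in deviance at the posterior means of the deviance's own
    # continuous parameters: the NB mean surface eta_it and the
    # overdispersion.  (Averaging the mixing latents and the intercept
    # separately is incoherent under the likelihood-invariant scale ridge
    # and can produce large negative P_D.)
    alpha_bar = sum(r["alpha_sum"] for r in results) / kept_total
    active = {"tau", "chi"} if spec.has_lindley else set()
    active |= {"Lam"} if spec.family == "NB-GE" else set()
    active |= {"j"} if spec.family == "RENB-L-alpha" else set()
    active |= {"intercept_re"} if spec.family == "RENB-L-intercept" else set()
    latent_means = {name: sum(r["latent_sums"][name] for r in results) / kept_total
                    for name in active}
    for name in spec.random_candidates:
        latent_means[f"w[{name}]"] = sum(r["w_sums"][name] for r in results) / kept_total
    from .distributions import nb_logpmf

    if cfg.likelihood_scale == 0.0:
        # prior-only runs have no meaningful deviance or fitted surface
        d_hat = float("nan")
        pd_eff = float("nan")
        dbar = float("nan")
    else:
        d_hat = float(-2.0 * np.sum(nb_logpmf(panel.y, fitted, alpha_bar)))
        if not np.isfinite(d_hat):
            raise McmcError("non-finite plug-in deviance at posterior means")
        pd_eff = dbar - d_hat
    acceptance = {k: float(np.mean([r["acceptance"].get(k, np.nan) for r in results]))
                  for k in results[0]["acceptance"]}
    return FitResult(
        spec=spec, config=cfg, draws=draws, summaries=summaries, rhat=rhat,
        dbar=float(dbar), pd_eff=float(pd_eff), dic=float(dbar + pd_eff),
        fitted=fitted, deviance_at_mean=float(d_hat), acceptance=acceptance,
        latent_means=latent_means,
    )
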