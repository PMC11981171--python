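"""Effect quantification: elasticities, marginal effects, and random-parameter
classification with sign-share decomposition.

For a continuous covariate x with coefficient beta, the elasticity is the
panel average of beta * x_it, interpreted as the percent change in expected
crash frequency per 1% change in x.  For a binary covariate, the marginal
effect is the panel average of beta * exp(beta * x_it) per km of mean segment
length: the change in crashes per kilometre per unit switch of the indicator.
Both are computed per posterior draw and summarized with 95% credible
intervals.

For random-parameters fits, a candidate coefficient is classified as random
when the 95% credible interval of its population standard deviation sigma
sits clearly above zero; the fitted Normal(mean, sigma) coefficient
population is then decomposed into the share of observations with a positive
coefficient, Phi(mean / sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import FitResult
from .panel import CrashPanel

__all__ = [
    "EffectError",
    "EffectTable",
    "elasticity",
    "marginal_effect",
    "effect_table",
    "positive_share",
    "classify_random",
]


class EffectError(ValueError):
    """Invalid effect computation request."""


@dataclass(frozen=True)
class EffectSummary:
    variable: str
    effect_type: str  # "elasticity" | "marginal"
    mean: float
    sd: float
    lower: float
    upper: float


def _coefficient_draws(fit: FitResult, var: str) -> np.ndarray:
    name = f"beta[{var}]"
    if name not in fit.draws.params:
        raise EffectError(f"{var!r} is not a modelled covariate of this fit")
    # For RPNB-L the population-mean coefficient draw is used, matching the
    # reporting convention of the effect formulas.
    return fit.draws.stacked(name)


def _summarize(var: str, kind: str, values: np.ndarray) -> EffectSummary:
    lo, hi = np.quantile(values, [0.025, 0.975])
    return EffectSummary(
        variable=var, effect_type=kind,
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        lower=float(lo), upper=float(hi),
    )


def elasticity(fit: FitResult, panel: CrashPanel, var: str) -> EffectSummary:
    """Posterior summary of E_x = mean over cells of beta * x_it.

    Only valid for continuous covariates; binary covariates are directed to
    :func:`marginal_effect`.
    """
    cov = panel.schema.lookup(var)
    if cov.kind != "continuous":
        raise EffectError(f"{var!r} is binary; use marginal_effect")
    x = panel.covariate_values(var)
    beta = _coefficient_draws(fit, var)
    values = beta * float(np.mean(x))
    return _summarize(var, "elasticity", values)


def marginal_effect(fit: FitResult, panel: CrashPanel, var: str) -> EffectSummary:
    """Posterior summary of M_x = mean over cells of beta * exp(beta x_it) / L.

    ``L`` is the mean segment length in km.  Only valid for binary covariates.
    """
    cov = panel.schema.lookup(var)
    if cov.kind != "binary":
        raise EffectError(f"{var!r} is continuous; use elasticity")
    x = panel.covariate_values(var)
    L = float(np.mean(panel.length_km))
    beta = _coefficient_draws(fit, var)
    # per draw: average of beta*exp(beta*x) over cells, per km
    values = beta * np.mean(np.exp(np.outer(beta, x)), axis=1) / L
    return _summarize(var, "marginal", values)


def effect_table(fit: FitResult, panel: CrashPanel, variables=None) -> pd.DataFrame:
    """Elasticity/marginal-effect report for the given (default: all) covariates."""
    variables = list(variables) if variables is not None else list(fit.spec.covariates)
    rows = []
    for var in variables:
        cov = panel.schema.lookup(var)
        es = (elasticity if cov.kind == "continuous" else marginal_effect)(fit, panel, var)
        rows.append({
            "variable": es.variable, "type": es.effect_type, "mean": es.mean,
            "sd": es.sd, "q2.5": es.lower, "q97.5": es.upper,
        })
    return pd.DataFrame(rows).set_index("variable")


def positive_share(mean: float, sd: float) -> float:
    """Share of a Normal(mean, sd) coefficient population above zero: Phi(mean/sd)."""
    if sd <= 0:
        raise EffectError("sd must be positive")
    return float(stats.norm.cdf(mean / sd))


def classify_random(fit: FitResult, sigma_floor: float = 0.05) -> pd.DataFrame:
    """Partition random candidates of an RPNB-L fit into random vs fixed.

    A candidate counts as random when the lower 95% bound of its coefficient
    sd sigma clears ``sigma_floor`` — i.e. the heterogeneity scale is
    significantly different from zero (sigma has positive support, so the
    floor separates genuine spread from posteriors piled up near zero).
    Returns a table with the sigma summary, the classification, and the
    positive/negative sign shares of the fitted coefficient population.
    """
    if fit.spec.family != "RPNB-L":
        raise EffectError("random-parameter classification requires an RPNB-L fit")
    rows = []
    for name in fit.spec.random_candidates:
        sig = fit.draws.stacked(f"sigma[{name}]")
        beta = fit.draws.stacked(f"beta[{name}]")
        lo, hi = np.quantile(sig, [0.025, 0.975])
        sig_mean = float(np.mean(sig))
        beta_mean = float(np.mean(beta))
        is_random = bool(lo > sigma_floor)
        share = positive_share(beta_mean, sig_mean) if sig_mean > 0 else float("nan")
        rows.append({
            "variable": name,
            "beta_mean": beta_mean,
            "sigma_mean": sig_mean,
            "sigma_q2.5": float(lo),
            "sigma_q97.5": float(hi),
            "random": is_random,
            "positive_share": share,
            "negative_share": 1.0 - share,
        })
    return pd.DataFrame(rows).set_index("variable")
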