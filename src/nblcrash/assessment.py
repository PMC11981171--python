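"""Goodness-of-fit (DIC) and prediction-accuracy (MAD, RMSE) comparison.

DIC = Dbar + P_D, where Dbar is the posterior mean of the deviance
(-2 log-likelihood of the NB kernel given the mixing latents) and
P_D = Dbar - D(posterior means) penalizes effective model complexity.
MAD and RMSE compare the fitted posterior-mean counts ybar_it with the
observed counts cell by cell; RMSE >= MAD always (power-mean inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import FitResult
from .panel import CrashPanel

__all__ = ["DicParts", "dic", "mad", "rmse", "compare", "AssessmentError"]


class AssessmentError(ValueError):
    """Invalid assessment input."""


@dataclass(frozen=True)
class DicParts:
    """DIC decomposition: posterior mean deviance, complexity penalty, total."""

    dbar: float
    pd: float
    dic: float


def dic(fit: FitResult) -> DicParts:
    """DIC of a fitted model: Dbar + P_D with P_D = Dbar - D(theta_bar)."""
    if not np.isfinite(fit.deviance_at_mean):
        raise AssessmentError("non-finite plug-in deviance")
    parts = DicParts(dbar=fit.dbar, pd=fit.pd_eff, dic=fit.dbar + fit.pd_eff)
    if not np.isclose(parts.dic, fit.dic):
        raise AssessmentError("fit carries an inconsistent DIC decomposition")
    return parts


def _fitted(fit: FitResult, panel: CrashPanel) -> np.ndarray:
    yhat = np.asarray(fit.fitted, dtype=float)
    if yhat.shape != (panel.n,):
        raise AssessmentError(
            f"fitted means cover {yhat.shape[0]} cells, panel has {panel.n}"
        )
    return yhat


def mad(fit: FitResult, panel: CrashPanel) -> float:
    """Mean absolute deviation (1/(I*T)) * sum |ybar - y|."""
    return float(np.mean(np.abs(_fitted(fit, panel) - panel.y)))


def rmse(fit: FitResult, panel: CrashPanel) -> float:
    """Root mean square error sqrt(sum (ybar - y)^2 / N)."""
    return float(np.sqrt(np.mean((_fitted(fit, panel) - panel.y) ** 2)))


def compare(fits: dict, panel: CrashPanel) -> pd.DataFrame:
    """Multi-model comparison table ranked by DIC (lower is better).

    ``fits`` maps a model label (typically the family name) to its
    :class:`FitResult`.  Columns: dbar, pd, dic, mad, rmse, rank.
    """
    if not fits:
        raise AssessmentError("no fits to compare")
    rows = []
    for label, fr in fits.items():
        parts = dic(fr)
        rows.append({
            "model": label,
            "dbar": parts.dbar,
            "pd": parts.pd,
            "dic": parts.dic,
            "mad": mad(fr, panel),
            "rmse": rmse(fr, panel),
        })
    out = pd.DataFrame(rows).set_index("model").sort_values("dic")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
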