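"""Segment-by-period crash panels: exposure construction, screening, and I/O.

A :class:`CrashPanel` is a balanced rectangular table with one row per
(segment, period) cell holding a non-negative crash count, the segment length
in km, and a set of named covariates.  Exposure covariates are built from raw
toll-gate vehicle counts: the five toll classes are weighted into
passenger-car equivalents (weights 1, 1.5, 2, 3, 3.5) to form the quarterly
average daily traffic (QADT) and the weighted composition shares of each
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TollCounts",
    "Covariate",
    "PanelSchema",
    "CrashPanel",
    "PanelError",
    "UnbalancedPanelError",
    "CollinearityResult",
    "PCE_WEIGHTS",
    "compute_qadt",
    "compute_vehicle_shares",
    "collinearity_screen",
    "read_panel",
    "write_panel",
]

#: Passenger-car-equivalent weights for toll vehicle classes 1..5.
PCE_WEIGHTS = (1.0, 1.5, 2.0, 3.0, 3.5)

KEY_COLUMNS = ("segment_id", "period", "y", "length_km")


class PanelError(ValueError):
    """Invalid panel contents (negative counts, duplicates, missing cells)."""


class UnbalancedPanelError(PanelError):
    """Panel is not a complete segment x period rectangle."""


@dataclass(frozen=True)
class TollCounts:
    """Raw toll-section vehicle counts for one segment-period.

    ``v1``..``v5`` are class 1-5 vehicle counts over the period; ``q`` is the
    number of days in the period.
    """

    v1: float
    v2: float
    v3: float
    v4: float
    v5: float
    q: int

    def __post_init__(self) -> None:
        counts = (self.v1, self.v2, self.v3, self.v4, self.v5)
        if any(c < 0 for c in counts):
            raise PanelError("vehicle counts must be non-negative")
        if self.q < 1:
            raise PanelError("q (days in period) must be >= 1")

    @property
    def weighted_total(self) -> float:
        return float(sum(w * c for w, c in zip(PCE_WEIGHTS, (self.v1, self.v2, self.v3, self.v4, self.v5))))


def compute_qadt(tc: TollCounts) -> float:
    """Quarterly average daily traffic: PCE-weighted count sum divided by days."""
    return tc.weighted_total / tc.q


def compute_vehicle_shares(tc: TollCounts) -> dict:
    """Weighted composition shares v_c / (v1 + 1.5 v2 + 2 v3 + 3 v4 + 3.5 v5).

    All five classes are returned (class 3 is computed even though the default
    modelling schema excludes it); the shares satisfy
    ``sum_c weight_c * share_c == 1`` exactly.
    """
    total = tc.weighted_total
    if total <= 0:
        raise PanelError("weighted vehicle total must be positive for shares")
    counts = (tc.v1, tc.v2, tc.v3, tc.v4, tc.v5)
    return {c + 1: counts[c] / total for c in range(5)}


@dataclass(frozen=True)
class Covariate:
    """One schema entry: name, kind ('continuous'|'binary'), transform.

    ``transform='log'`` means the model uses ``ln(raw)``; raw values are kept
    in the table and the transformed column is derived on demand.
    """

    name: str
    kind: str = "continuous"
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise PanelError(f"covariate {self.name}: kind must be continuous|binary")
        if self.transform not in ("identity", "log"):
            raise PanelError(f"covariate {self.name}: transform must be identity|log")
        if self.kind == "binary" and self.transform == "log":
            raise PanelError(f"covariate {self.name}: log transform on a binary covariate")

    @property
    def model_name(self) -> str:
        return f"ln_{self.name}" if self.transform == "log" else self.name


@dataclass(frozen=True)
class PanelSchema:
    """Declared covariate catalogue of a panel."""

    covariates: tuple

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise PanelError("duplicate covariate names in schema")

    def __iter__(self):
        return iter(self.covariates)

    @property
    def names(self) -> list:
        return [c.name for c in self.covariates]

    @property
    def model_names(self) -> list:
        return [c.model_name for c in self.covariates]

    def lookup(self, model_name: str) -> Covariate:
        for c in self.covariates:
            if c.model_name == model_name or c.name == model_name:
                return c
        raise PanelError(f"covariate {model_name!r} not in schema")


class CrashPanel:
    """Balanced segment x period crash panel.

    Parameters
    ----------
    df : DataFrame with columns segment_id, period, y, length_km plus one
        column per schema covariate (raw scale).
    schema : PanelSchema describing the covariates.
    """

    def __init__(self, df: pd.DataFrame, schema: PanelSchema):
        missing = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"missing required columns: {missing}")
        for cov in schema:
            if cov.name not in df.columns:
                raise PanelError(f"schema covariate {cov.name!r} missing from table")
        df = df.copy()
        if df[list(KEY_COLUMNS) + schema.names].isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise PanelError(f"missing cells in columns {bad}")
        y = df["y"].to_numpy()
        if not np.allclose(y, np.round(y)) or (y < 0).any():
            raise PanelError("crash counts y must be non-negative integers")
        df["y"] = np.round(y).astype(np.int64)
        if (df["length_km"].to_numpy() <= 0).any():
            raise PanelError("length_km must be positive")
        dup = df.duplicated(subset=["segment_id", "period"])
        if dup.any():
            keys = df.loc[dup, ["segment_id", "period"]].to_records(index=False).tolist()
            raise PanelError(f"duplicate (segment, period) keys: {keys[:5]}")
        segments = sorted(df["segment_id"].unique().tolist())
        periods = sorted(df["period"].unique().tolist())
        expected = {(s, p) for s in segments for p in periods}
        present = set(zip(df["segment_id"], df["period"]))
        gaps = sorted(expected - present)
        if gaps:
            raise UnbalancedPanelError(
                f"panel is unbalanced; missing (segment, period) cells: {gaps[:10]}"
            )
        self.df = df.sort_values(["segment_id", "period"], kind="mergesort").reset_index(drop=True)
        self.schema = schema
        self.segments = segments
        self.periods = periods

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol for segment count
        return len(self.segments)

    @property
    def T(self) -> int:
        return len(self.periods)

    @property
    def n(self) -> int:
        """Total cell count N = I x T."""
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy()

    @property
    def length_km(self) -> np.ndarray:
        return self.df["length_km"].to_numpy(dtype=float)

    def covariate_values(self, model_name: str) -> np.ndarray:
        """Covariate column on the model scale (log-transformed if declared)."""
        cov = self.schema.lookup(model_name)
        raw = self.df[cov.name].to_numpy(dtype=float)
        if cov.transform == "log":
            if (raw <= 0).any():
                raise PanelError(f"log transform of non-positive values in {cov.name}")
            return np.log(raw)
        return raw

    def design_matrix(self, model_names: list) -> np.ndarray:
        """Column-stacked model-scale covariates, shape (n, len(model_names))."""
        return np.column_stack([self.covariate_values(m) for m in model_names])

    def zero_fraction(self) -> float:
        return float(np.mean(self.y == 0))


@dataclass
class CollinearityResult:
    """Output of the pairwise collinearity screen."""

    flagged: list = field(default_factory=list)  # (name_a, name_b, r)
    degenerate: list = field(default_factory=list)  # constant covariates

    @property
    def flagged_pairs(self) -> list:
        return [(a, b) for a, b, _ in self.flagged]


def collinearity_screen(panel: CrashPanel, threshold: float = 0.7) -> CollinearityResult:
    """Flag covariate pairs with |Pearson r| >= threshold on the model scale.

    Binary covariates enter through their 0/1 coding.  Constant covariates
    cannot be tested and are reported as degenerate rather than dropped.
    """
    if not 0.0 < threshold < 1.0:
        raise PanelError("threshold must lie in (0, 1)")
    names = panel.schema.model_names
    if len(names) < 2:
        raise PanelError("collinearity screen needs at least 2 covariates")
    cols = {m: panel.covariate_values(m) for m in names}
    result = CollinearityResult()
    for m in names:
        if np.std(cols[m]) == 0.0:
            result.degenerate.append(m)
    testable = [m for m in names if m not in result.degenerate]
    for i, a in enumerate(testable):
        for b in testable[i + 1:]:
            r = float(np.corrcoef(cols[a], cols[b])[0, 1])
            if abs(r) >= threshold:
                result.flagged.append((a, b, r))
    return result


def write_panel(panel: CrashPanel, path) -> None:
    """Write the panel as UTF-8 CSV with a header row."""
    panel.df.to_csv(path, index=False)


def read_panel(path, schema: PanelSchema) -> CrashPanel:
    """Read a delimited panel file and validate it against ``schema``.

    Raises distinct errors for missing cells, negative counts, duplicate
    (segment, period) keys, and unbalanced panels (naming the gaps).
    """
    df = pd.read_csv(path)
    return CrashPanel(df, schema)
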