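"""Variable standardization, derived ultrasound summaries, and dataset splitting.

Z-standardization stores training means/SDs so that a new cohort can be scaled
with the *training* statistics (required for the stacking predictor to
transfer); the dichotomizer maps a Z-score to low/high around the standardized
mean with ties at exactly zero labelled high.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CohortTable

__all__ = [
    "Standardizer",
    "z_standardize",
    "dichotomize",
    "split_complete_cases",
    "derive_ultrasound_summaries",
    "DatasetSplit",
]


@dataclass
class Standardizer:
    """Per-variable Z-scaling with stored (mean, sd); sample SD (n-1)."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.means)

    def fit(self, df: pd.DataFrame, variables) -> "Standardizer":
        for v in variables:
            col = pd.to_numeric(df[v], errors="raise").to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(f"variable {v!r} has missing values; split complete cases first")
            sd = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
            if sd == 0.0 or not np.isfinite(sd):
                raise ValueError(f"variable {v!r} has zero variance and cannot be standardized")
            self.means[v] = float(np.mean(col))
            self.sds[v] = sd
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [v for v in self.variables if v not in df.columns]
        if missing:
            raise ValueError(f"columns absent from table: {missing}")
        out = {v: (df[v].to_numpy(dtype=float) - self.means[v]) / self.sds[v] for v in self.variables}
        return pd.DataFrame(out, index=df.index)

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        out = {v: z[v].to_numpy(dtype=float) * self.sds[v] + self.means[v] for v in self.variables}
        return pd.DataFrame(out, index=z.index)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"means": self.means, "sds": self.sds}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "Standardizer":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(means=d["means"], sds=d["sds"])


def z_standardize(table: CohortTable | pd.DataFrame, variables=None) -> tuple[pd.DataFrame, Standardizer]:
    """Z = (value - mean) / sd per variable; returns scores and the fitted scaler."""
    df = table.data if isinstance(table, CohortTable) else table
    if variables is None:
        if not isinstance(table, CohortTable):
            raise ValueError("variables must be given for a plain DataFrame")
        variables = table.analysis_variables()
    scaler = Standardizer().fit(df, variables)
    return scaler.transform(df), scaler


def dichotomize(z) -> np.ndarray:
    """'low' if Z < 0, 'high' if Z >= 0 (tie at the standardized mean -> high)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("dichotomize requires finite Z-scores")
    return np.where(z < 0, "low", "high")


@dataclass
class DatasetSplit:
    """Complete-case ('derived') vs any-missing ('replicated') subject ids."""

    derived: np.ndarray
    replicated: np.ndarray


def split_complete_cases(table: CohortTable, variables) -> DatasetSplit:
    """Partition subjects by missingness among the listed analysis variables."""
    variables = list(variables)
    if not variables:
        raise ValueError("variable list must be non-empty")
    absent = [v for v in variables if v not in table.data.columns]
    if absent:
        raise ValueError(f"unknown variables: {absent}")
    ids = table.data["subject_id"].to_numpy()
    any_missing = table.data[variables].isna().any(axis=1).to_numpy()
    return DatasetSplit(derived=ids[~any_missing], replicated=ids[any_missing])


def derive_ultrasound_summaries(segment_maxima, progression=None) -> pd.DataFrame:
    """Derived carotid measures from per-segment data.

    ``cimt_mean_max`` = mean of per-segment maxima; ``cimt_max`` = the largest
    segment; ``fastest_prog`` = the fastest-progressing segment's annual
    change, also returned log-transformed as log10(fastest + 0.1).
    """
    seg = np.atleast_2d(np.asarray(segment_maxima, dtype=float))
    if seg.shape[1] == 0:
        raise ValueError("at least one ultrasound segment per subject is required")
    out = pd.DataFrame({
        "cimt_mean_max": seg.mean(axis=1),
        "cimt_max": seg.max(axis=1),
    })
    if progression is not None:
        prog = np.atleast_2d(np.asarray(progression, dtype=float))
        if prog.shape[0] != seg.shape[0]:
            raise ValueError("progression rows must align with baseline rows")
        fastest = prog.max(axis=1)
        shifted = fastest + 0.1
        if np.any(shifted <= 0):
            raise ValueError("log10(fastest + 0.1) undefined: fastest progression <= -0.1")
        out["fastest_prog"] = fastest
        out["log_fastest_prog"] = np.log10(shifted)
    return out


def cohort_summaries(table: CohortTable) -> pd.DataFrame:
    """Convenience: derived ultrasound summaries for a generated cohort table."""
    seg_cols = [c for c in table.data.columns if c.startswith("cimt_segment_max_")]
    prog_cols = [c for c in table.data.columns if c.startswith("cimt_prog_segment_")]
    return derive_ultrasound_summaries(
        table.data[seg_cols].to_numpy(),
        table.data[prog_cols].to_numpy() if prog_cols else None,
    )
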