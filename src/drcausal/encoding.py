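"""Design-matrix encoding for the causal analysis.

The confounder vector L collects categorical demographics (age group at
diagnosis, sex, race, marital status — "Unknown" is a legitimate level) and
binary comorbidity flags.  Categoricals are reference-coded: the first level
in the documented level order is dropped, so a field with k levels
contributes k-1 indicator columns.  The intercept is always column 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CovariateSchema", "AnalysisMatrix", "build_analysis_matrix", "EncodingError"]


class EncodingError(ValueError):
    """Raised when data do not match the documented schema."""


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate fields and their level orders.

    ``fields`` maps field name -> tuple of levels, in reference-first order.
    Binary flags use levels (0, 1) so the "present" indicator is kept.
    """

    fields: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        for name, levels in self.fields.items():
            if len(levels) < 2:
                raise EncodingError(f"covariate {name!r} needs >= 2 levels")
            if len(set(levels)) != len(levels):
                raise EncodingError(f"covariate {name!r} has duplicate levels")

    @property
    def names(self) -> list[str]:
        return list(self.fields)

    @property
    def n_columns(self) -> int:
        """Encoded width including the intercept."""
        return 1 + sum(len(v) - 1 for v in self.fields.values())

    def column_names(self) -> list[str]:
        cols = ["intercept"]
        for name, levels in self.fields.items():
            cols.extend(f"{name}[{lv}]" for lv in levels[1:])
        return cols

    def column_groups(self) -> dict[str, list[int]]:
        """Field name -> indices of its columns in the encoded matrix."""
        groups: dict[str, list[int]] = {}
        j = 1
        for name, levels in self.fields.items():
            groups[name] = list(range(j, j + len(levels) - 1))
            j += len(levels) - 1
        return groups

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.fields if c not in df.columns]
        if missing:
            raise EncodingError(f"input table lacks required column(s): {missing}")
        n = len(df)
        L = np.zeros((n, self.n_columns))
        L[:, 0] = 1.0
        j = 1
        for name, levels in self.fields.items():
            col = df[name]
            if col.isna().any():
                raise EncodingError(
                    f"column {name!r} has missing values; 'Unknown' is a valid "
                    "level but absent data is not"
                )
            values = col.to_numpy()
            known = np.isin(values, np.asarray(levels, dtype=object))
            if not known.all():
                bad = sorted(set(values[~known]))
                raise EncodingError(f"column {name!r} has unknown level(s) {bad}")
            for lv in levels[1:]:
                L[:, j] = values == lv
                j += 1
        return L


@dataclass
class AnalysisMatrix:
    """Encoded analysis data: outcome Y, treatment A, confounder design L."""

    Y: np.ndarray
    A: np.ndarray
    L: np.ndarray
    schema: CovariateSchema
    columns: list[str]

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.A = np.asarray(self.A, dtype=int)
        self.L = np.asarray(self.L, dtype=float)
        n = self.L.shape[0]
        if self.Y.shape != (n,) or self.A.shape != (n,):
            raise EncodingError("Y, A and L row counts disagree")
        if np.isnan(self.Y).any() or np.isnan(self.L).any():
            raise EncodingError("missing entries are not allowed in Y or L")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise EncodingError("Y must be binary 0/1")
        if not np.isin(self.A, (0, 1, 2, 3)).all():
            raise EncodingError("treatment must take values in {0,1,2,3}")

    @property
    def n(self) -> int:
        return self.L.shape[0]


def build_analysis_matrix(
    df: pd.DataFrame,
    schema: CovariateSchema,
    outcome_col: str = "y5_survival",
    treatment_col: str = "treatment",
) -> AnalysisMatrix:
    """Encode a filtered patient-level table into (Y, A, L)."""
    for c in (outcome_col, treatment_col):
        if c not in df.columns:
            raise EncodingError(f"input table lacks required column {c!r}")
    L = schema.encode(df)
    return AnalysisMatrix(
        Y=df[outcome_col].to_numpy(),
        A=df[treatment_col].to_numpy(),
        L=L,
        schema=schema,
        columns=schema.column_names(),
    )
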