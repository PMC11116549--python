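"""Eligibility filters and descriptive summaries for patient-level tables.

The entry point is an analysis table, one row per patient, with a first
diagnosis date, demographics (where "Unknown" is a valid level but a
missing value is not), a medication history, the five-year survival
indicator and follow-up years.  ``apply_study_filters`` applies the study's
eligibility contract in a documented order and reports per-step counts;
``treatment_frequency_table`` and ``mortality_rate`` reproduce the two
descriptive tables (medication shares, deaths per 1000 patient-years).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import TREATMENT_LABELS

__all__ = [
    "FilterReport",
    "SchemaError",
    "apply_study_filters",
    "treatment_frequency_table",
    "mortality_rate",
    "round_half_up",
]

REQUIRED_DEMOGRAPHICS = ("age_group", "sex", "race", "marital_status")

# strategy taxonomy: 0 = no drug, 1 = Memantine, 2 = Donepezil, 3 = combined
STRATEGY_CODES = {label: code for code, label in enumerate(TREATMENT_LABELS)}


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass
class FilterReport:
    """Ordered per-step record counts of the eligibility filter chain."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def final_n(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError("filter steps cannot increase record counts")
        if self.steps and n_in != self.steps[-1][2]:
            raise ValueError("filter chain counts must be contiguous")
        self.steps.append((name, int(n_in), int(n_out)))

    def to_json(self, path=None) -> str:
        doc = {
            "steps": [
                {"filter": s, "records_in": a, "records_out": b}
                for s, a, b in self.steps
            ],
            "final_n": self.final_n,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, mirroring how the summary tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _parse_regimens(history) -> list[str]:
    """Medication history -> ordered distinct regimen labels.

    The history is a '|'-separated sequence of regimen labels observed over
    follow-up (a single label for never-switchers).  An empty history means
    the no-drug strategy.
    """
    if history is None or (isinstance(history, float) and np.isnan(history)):
        return ["none"]
    text = str(history).strip()
    if not text:
        return ["none"]
    out = []
    for token in text.split("|"):
        token = token.strip()
        if token and token not in out:
            out.append(token)
    return out or ["none"]


def apply_study_filters(
    records: pd.DataFrame,
    dx_window: tuple[str, str] = ("2016-01-01", "2016-12-31"),
    required_demographics: tuple[str, ...] = REQUIRED_DEMOGRAPHICS,
    allowed_treatments: dict[str, int] = STRATEGY_CODES,
    min_treatment_share: float = 0.005,
    drop_switchers: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the eligibility contract; return (filtered table, report).

    Steps, in order: (1) first diagnosis inside the inclusive calendar
    window; (2) complete demographics — "Unknown" passes, a missing value
    does not; (3) drop treatment switchers (more than one distinct regimen
    over follow-up); (4) keep only the allowed strategies and assign the
    integer treatment code; (5) drop any strategy used by less than
    ``min_treatment_share`` of the post-switcher cohort.  Empty input is a
    valid input (empty output, full report).
    """
    for col in ("first_dx_date", "med_history"):
        if col not in records.columns:
            raise SchemaError(f"input table lacks required column {col!r}")
    for col in required_demographics:
        if col not in records.columns:
            raise SchemaError(f"input table lacks required column {col!r}")

    report = FilterReport()
    df = records.copy()

    n0 = len(df)
    dates = pd.to_datetime(df["first_dx_date"], errors="coerce")
    lo, hi = pd.Timestamp(dx_window[0]), pd.Timestamp(dx_window[1])
    df = df[(dates >= lo) & (dates <= hi)]
    report.add("first_dx_in_window", n0, len(df))

    n1 = len(df)
    complete = np.ones(len(df), dtype=bool)
    for col in required_demographics:
        vals = df[col]
        complete &= (~vals.isna() & (vals.astype(str).str.strip() != "")).to_numpy()
    df = df[complete]
    report.add("complete_demographics", n1, len(df))

    n2 = len(df)
    regimens = [_parse_regimens(h) for h in df["med_history"]]
    if drop_switchers:
        keep = np.array([len(r) == 1 for r in regimens], dtype=bool)
        df = df[keep]
        regimens = [r for r, k in zip(regimens, keep) if k]
    report.add("drop_switchers", n2, len(df))
    n_post_switch = len(df)

    n3 = len(df)
    final_regimen = np.array([r[0] for r in regimens], dtype=object)
    keep = np.array([r in allowed_treatments for r in final_regimen], dtype=bool)
    df = df[keep].copy()
    final_regimen = final_regimen[keep]
    df["treatment"] = [allowed_treatments[r] for r in final_regimen]
    report.add("allowed_treatment_strategies", n3, len(df))

    n4 = len(df)
    if n_post_switch > 0 and len(df) > 0:
        shares = pd.Series(final_regimen).value_counts() / n_post_switch
        rare = set(shares[shares < min_treatment_share].index)
        keep = ~np.isin(final_regimen, list(rare))
        df = df[keep]
    report.add("min_treatment_share", n4, len(df))

    return df.reset_index(drop=True), report


def treatment_frequency_table(
    records: pd.DataFrame, label_col: str = "treatment"
) -> pd.DataFrame:
    """Counts and percent-of-total per treatment label (two-decimal, half-up)."""
    if label_col not in records.columns:
        raise SchemaError(f"input table lacks required column {label_col!r}")
    labels = records[label_col]
    if label_col == "treatment":
        labels = labels.map(lambda a: TREATMENT_LABELS[int(a)])
    counts = labels.value_counts()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "label": counts.index,
            "count": counts.to_numpy(),
            "percent": [round_half_up(100.0 * c / total) for c in counts],
        }
    ).reset_index(drop=True)


def mortality_rate(
    records: pd.DataFrame, group_by: str = "treatment"
) -> pd.DataFrame:
    """Deaths per 1000 patient-years, per group and in total.

    A group with zero person-time gets a NaN rate rather than an error.
    Invariant to record order.
    """
    for col in ("y5_survival", "followup_years", group_by):
        if col not in records.columns:
            raise SchemaError(f"input table lacks required column {col!r}")

    def _rate(sub: pd.DataFrame) -> tuple[int, float, float]:
        deaths = int((sub["y5_survival"] == 0).sum())
        py = float(sub["followup_years"].sum())
        rate = 1000.0 * deaths / py if py > 0 else float("nan")
        return deaths, py, rate

    rows = []
    for key in sorted(records[group_by].unique()):
        deaths, py, rate = _rate(records[records[group_by] == key])
        label = TREATMENT_LABELS[int(key)] if group_by == "treatment" else key
        rows.append({"group": label, "deaths": deaths, "person_years": py, "rate_per_1000py": rate})
    deaths, py, rate = _rate(records)
    rows.append({"group": "total", "deaths": deaths, "person_years": py, "rate_per_1000py": rate})
    return pd.DataFrame(rows)
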