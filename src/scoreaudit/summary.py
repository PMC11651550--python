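"""Descriptive cohort summaries stratified by group, one column per group.

Percentages use the whole group (missing values included) as denominator,
so complementary percentages over the non-missing categories of a variable
sum to 100 minus the missing percentage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .groups import GroupSpec, assign_group
from .schema import NA_TOKEN, CohortTable

SUMMARY_ROWS = [
    "n_thousand",
    "percent_male",
    "age_mean",
    "age_sd",
    "percent_most_deprived",
    "percent_least_deprived",
    "percent_white",
    "percent_nonwhite",
    "percent_ethnicity_missing",
    "percent_urban",
    "percent_rural",
    "percent_mainland",
    "percent_island",
]


def _summarise_one(df: pd.DataFrame) -> dict[str, float]:
    n = len(df)
    if n == 0:
        return {row: np.nan for row in SUMMARY_ROWS}
    pct = lambda mask: 100.0 * float(np.count_nonzero(mask)) / n
    return {
        "n_thousand": n / 1000.0,
        "percent_male": pct(df["sex"] == "M"),
        "age_mean": float(df["age"].mean()),
        "age_sd": float(df["age"].std(ddof=1)) if n > 1 else np.nan,
        "percent_most_deprived": pct(df["simd_decile"].isin((1, 2))),
        "percent_least_deprived": pct(df["simd_decile"].isin((9, 10))),
        "percent_white": pct(df["ethnicity"] == "white"),
        "percent_nonwhite": pct(df["ethnicity"] == "nonwhite"),
        "percent_ethnicity_missing": pct(df["ethnicity"] == NA_TOKEN),
        "percent_urban": pct(df["urban_rural"] == "urban"),
        "percent_rural": pct(df["urban_rural"] == "rural"),
        "percent_mainland": pct(df["mainland_island"] == "mainland"),
        "percent_island": pct(df["mainland_island"] == "island"),
    }


def summarize_cohort(
    table: CohortTable, specs: list[GroupSpec] | None = None
) -> pd.DataFrame:
    """Build a descriptive summary table: rows are statistics, columns are
    the whole cohort (``All``) followed by each group of each spec.

    An empty group yields a column of missing values with a warning.
    """
    if len(table) == 0:
        raise ValueError("cohort is empty")
    cols: dict[str, dict[str, float]] = {"All": _summarise_one(table.df)}
    for spec in specs or []:
        labels = assign_group(table, spec)
        for lab in (spec.label_a, spec.label_b):
            sub = table.df[labels == lab]
            if len(sub) == 0:
                warnings.warn(
                    f"group {lab!r} of {spec.variable!r} is empty", stacklevel=2
                )
            cols[f"{spec.variable}:{lab}"] = _summarise_one(sub)
    return pd.DataFrame(cols).reindex(SUMMARY_ROWS)
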