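"""Demographic group definitions and per-row group assignment.

Each comparison contrasts two labelled groups defined on one grouping
variable; rows matching neither predicate (including rows with a missing
value for that variable) are excluded from the comparison. The six
built-in comparisons contrast the extremes of each variable: sex M/F,
age >=65 vs <=25, most vs least deprived SIMD quintile (built from the top
and bottom two deciles), white vs nonwhite ethnicity, urban vs rural, and
mainland vs island residence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .schema import NA_TOKEN, CohortTable

EXCLUDED = "excluded"


@dataclass(frozen=True)
class GroupSpec:
    """A two-group comparison on one grouping variable.

    ``predicate_a`` / ``predicate_b`` map a cohort frame to boolean masks;
    they must be disjoint. Rows matching neither are labelled ``excluded``.
    """

    variable: str
    label_a: str
    label_b: str
    predicate_a: Callable[[pd.DataFrame], pd.Series]
    predicate_b: Callable[[pd.DataFrame], pd.Series]

    def __repr__(self) -> str:  # callables are noise in reprs
        return f"GroupSpec({self.variable}: {self.label_a} vs {self.label_b})"


def _cat(col: str, value: str) -> Callable[[pd.DataFrame], pd.Series]:
    return lambda df: df[col] == value


BUILTIN_SPECS: dict[str, GroupSpec] = {
    "sex": GroupSpec("sex", "M", "F", _cat("sex", "M"), _cat("sex", "F")),
    "age": GroupSpec(
        "age",
        "over65",
        "under25",
        lambda df: df["age"] >= 65,
        lambda df: df["age"] <= 25,
    ),
    "deprivation": GroupSpec(
        "deprivation",
        "most_deprived",
        "least_deprived",
        lambda df: df["simd_decile"].isin((1, 2)),
        lambda df: df["simd_decile"].isin((9, 10)),
    ),
    "ethnicity": GroupSpec(
        "ethnicity", "white", "nonwhite",
        _cat("ethnicity", "white"), _cat("ethnicity", "nonwhite"),
    ),
    "urban_rural": GroupSpec(
        "urban_rural", "urban", "rural",
        _cat("urban_rural", "urban"), _cat("urban_rural", "rural"),
    ),
    "mainland_island": GroupSpec(
        "mainland_island", "mainland", "island",
        _cat("mainland_island", "mainland"), _cat("mainland_island", "island"),
    ),
}


class OverlappingPredicatesError(ValueError):
    """The two membership predicates both match at least one row."""


def assign_group(table: CohortTable, spec: GroupSpec) -> pd.Series:
    """Label every row ``label_a``, ``label_b`` or ``excluded``.

    Missing values (the ``NA`` sentinel) never match a categorical
    predicate, so they fall into ``excluded`` automatically.
    """
    df = table.df
    a = spec.predicate_a(df).to_numpy(bool)
    b = spec.predicate_b(df).to_numpy(bool)
    if (a & b).any():
        row = int(np.flatnonzero(a & b)[0])
        raise OverlappingPredicatesError(
            f"{spec!r}: predicates overlap at row {row}"
        )
    labels = np.where(a, spec.label_a, np.where(b, spec.label_b, EXCLUDED))
    return pd.Series(labels, index=df.index, name=spec.variable)


def group_masks(table: CohortTable, spec: GroupSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the two groups, in (a, b) order."""
    labels = assign_group(table, spec)
    return (
        (labels == spec.label_a).to_numpy(),
        (labels == spec.label_b).to_numpy(),
    )
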