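"""Age-band x sex x SIMD-decile strata for reweighting and standardisation.

A :class:`StrataDistribution` holds probability weights over the occupied
cells; it is the "fixed distribution" to which counterfactual score
distributions and adjusted error rates are standardised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import CohortTable

#: Default 5-year bands 0-4, 5-9, ..., 85-89, 90+.
DEFAULT_AGE_BANDS = np.arange(0, 95, 5)


def age_band_index(ages: np.ndarray, age_bands: np.ndarray) -> np.ndarray:
    """Index of the band containing each age; the last band is open above."""
    edges = np.asarray(age_bands, float)
    return np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 1)


#: Full strata components; comparisons defined on one of these drop that
#: component (a group cannot be reweighted onto the other group's value of
#: the variable that defines it).
ALL_COMPONENTS = ("age", "sex", "simd")


def stratum_keys(
    df: pd.DataFrame,
    age_bands: np.ndarray = DEFAULT_AGE_BANDS,
    components: tuple[str, ...] = ALL_COMPONENTS,
) -> pd.Series:
    """One hashable key per row over the requested components, by default
    (age band index, sex, SIMD decile)."""
    if not components or any(c not in ALL_COMPONENTS for c in components):
        raise ValueError(f"components must be a non-empty subset of {ALL_COMPONENTS}")
    parts = []
    if "age" in components:
        parts.append(age_band_index(df["age"].to_numpy(), age_bands).tolist())
    if "sex" in components:
        parts.append(df["sex"].tolist())
    if "simd" in components:
        parts.append(df["simd_decile"].tolist())
    return pd.Series(list(zip(*parts)), index=df.index)


@dataclass
class StrataDistribution:
    """Probability weights over occupied (age band, sex, decile) cells."""

    weights: pd.Series  # index: stratum key tuples; values sum to 1

    def __post_init__(self):
        w = self.weights
        if len(w) == 0:
            raise ValueError("no occupied strata")
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")

    def restrict(self, keys) -> tuple["StrataDistribution", float]:
        """Renormalise onto the given cells; returns (restricted, dropped mass)."""
        kept = self.weights[self.weights.index.isin(set(keys))]
        dropped = 1.0 - float(kept.sum())
        if kept.sum() <= 0:
            raise ValueError("no common stratum between distributions")
        return StrataDistribution(kept / kept.sum()), max(dropped, 0.0)


def strata_distribution(
    table: CohortTable,
    rows: np.ndarray,
    age_bands: np.ndarray = DEFAULT_AGE_BANDS,
    components: tuple[str, ...] = ALL_COMPONENTS,
) -> StrataDistribution:
    """Empirical strata frequencies among the rows selected by the mask."""
    rows = np.asarray(rows, bool)
    if not rows.any():
        raise ValueError("empty group membership")
    keys = stratum_keys(table.df.loc[rows], age_bands, components)
    counts = keys.value_counts()
    return StrataDistribution(counts / counts.sum())
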