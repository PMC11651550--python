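"""Demographic parity: score-distribution curves and counterfactual
(covariate-reweighted) score distributions.

The parity curve for a group is the empirical CDF of its scores on the
cutoff grid, P(score < c | group), with pointwise Wilson bounds. The
counterfactual curve asks what the comparison group's score distribution
would look like if it carried the target group's joint (age band, sex,
SIMD decile) distribution: a stratified average of the comparison group's
within-stratum CDFs under the target group's strata weights. Differences
between the raw and counterfactual curves isolate group effects not
mediated through age, sex and deprivation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .curves import CurveWithCI, CutoffGrid, proportion_curve
from .schema import CohortTable
from .strata import (
    ALL_COMPONENTS, DEFAULT_AGE_BANDS, StrataDistribution,
    strata_distribution, stratum_keys,
)

logger = logging.getLogger(__name__)


def _bin_counts(scores: np.ndarray, grid: CutoffGrid) -> np.ndarray:
    """Counts per grid bin: bin 0 = [0, c1), bin j = [c_j, c_{j+1}), last
    bin = [c_K, 1). CDF at c_k is the cumulative count of bins < k."""
    edges = np.concatenate(([0.0], grid.cutoffs, [1.0]))
    counts, _ = np.histogram(scores, bins=edges)
    return counts.astype(np.int64)


def score_cdf(
    scores: np.ndarray, grid: CutoffGrid, *, group: str = ""
) -> CurveWithCI:
    """Empirical CDF of a group's scores: fraction strictly below each
    cutoff, with pointwise 95% Wilson bounds at the group size."""
    scores = np.asarray(scores, float)
    if len(scores) == 0:
        raise ValueError("empty group")
    below = np.searchsorted(np.sort(scores), grid.cutoffs, side="left")
    n = np.full(len(grid), float(len(scores)))
    return proportion_curve(
        below.astype(float), n, grid, {"metric": "score_cdf", "group": group}
    )


def counterfactual_cdf(
    table: CohortTable,
    target_rows: np.ndarray,
    source_rows: np.ndarray,
    grid: CutoffGrid,
    age_bands: np.ndarray = DEFAULT_AGE_BANDS,
    *,
    components: tuple[str, ...] = ALL_COMPONENTS,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    group: str = "",
) -> CurveWithCI:
    """Score CDF of the source group reweighted to the target group's
    strata distribution.

    estimate(c) = sum_s w_target(s) * CDF_{source, s}(c), over strata
    occupied by the source group; target-group mass on strata the source
    group does not occupy is dropped with a logged warning and the
    remaining weights renormalised. Pointwise 95% bounds come from a
    stratified bootstrap (resampling individuals within each source
    stratum; percentile intervals).
    """
    target_rows = np.asarray(target_rows, bool)
    source_rows = np.asarray(source_rows, bool)
    if not target_rows.any() or not source_rows.any():
        raise ValueError("both groups must be non-empty")
    rng = rng if rng is not None else np.random.default_rng()

    w_target = strata_distribution(table, target_rows, age_bands, components)
    src = table.df.loc[source_rows]
    src_keys = stratum_keys(src, age_bands, components)
    occupied = src_keys.unique()
    weights, dropped = w_target.restrict(occupied)
    if dropped > 1e-12:
        logger.warning(
            "counterfactual reweighting dropped %.4f of target-group mass "
            "(strata empty in source group)", dropped,
        )

    k = len(grid)
    estimate = np.zeros(k)
    boot = np.zeros((n_boot, k))
    scores = src["score"].to_numpy(float)
    for key, w in weights.weights.items():
        s = scores[(src_keys == key).to_numpy()]
        n_s = len(s)
        counts = _bin_counts(s, grid)
        cdf = np.cumsum(counts)[:k] / n_s
        estimate += w * cdf
        reps = rng.multinomial(n_s, counts / n_s, size=n_boot)
        boot += w * (np.cumsum(reps, axis=1)[:, :k] / n_s)
    lower = np.quantile(boot, 0.025, axis=0)
    upper = np.quantile(boot, 0.975, axis=0)
    n_eff = np.full(k, float(source_rows.sum()))
    curve = CurveWithCI(
        grid, estimate, lower, upper, n_eff,
        {"metric": "counterfactual_cdf", "group": group, "adjusted": True},
    )
    curve.dropped_mass = np.full(k, dropped)
    return curve
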