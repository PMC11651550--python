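"""False omission and false discovery rate curves, raw and standardised.

Under the decision rule "predict an event iff score >= c":

* FOR(c) = P(Y = 1 | score < c): among those predicted negative, the
  fraction who had the event (the false-negative burden of the rule);
* FDR(c) = P(Y = 0 | score >= c): among those predicted positive, the
  fraction who did not (1 - precision).

The "adjusted" versions directly standardise the within-stratum rates to
a fixed reference distribution over (age band, sex, SIMD decile) cells,
removing between-group differences mediated by those covariates. Rates
are undefined (NaN, never zero) at cutoffs where nobody conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .curves import CurveWithCI, CutoffGrid, proportion_curve
from .schema import CohortTable
from .strata import (
    ALL_COMPONENTS, DEFAULT_AGE_BANDS, StrataDistribution,
    strata_distribution, stratum_keys,
)

logger = logging.getLogger(__name__)

REFERENCE_CHOICES = ("pooled_pair", "other_group", "self")


@dataclass
class RateCurveRequest:
    """What to compute: metric, grid, and (optionally) standardisation.

    ``reference`` names the strata distribution the adjusted curve is
    standardised to: the pooled distribution of the two compared groups
    (default, making the pair's adjusted curves commensurable), the
    comparator group, or the group itself.
    """

    metric: str  # "FOR" or "FDR"
    grid: CutoffGrid
    adjustment: str = "none"  # "none" | "standardised"
    reference: str = "pooled_pair"
    age_bands: np.ndarray = field(default_factory=lambda: DEFAULT_AGE_BANDS)
    components: tuple = ALL_COMPONENTS
    n_boot: int = 1000

    def __post_init__(self):
        if self.metric not in ("FOR", "FDR"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.adjustment not in ("none", "standardised"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        if self.reference not in REFERENCE_CHOICES:
            raise ValueError(f"unknown reference {self.reference!r}")


def _below_counts(
    scores: np.ndarray, outcomes: np.ndarray, grid: CutoffGrid
) -> tuple[np.ndarray, np.ndarray]:
    """(events below c, rows below c) for every grid cutoff."""
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], outcomes[order]
    pos = np.searchsorted(s, grid.cutoffs, side="left")
    cum_events = np.concatenate(([0], np.cumsum(y)))
    return cum_events[pos].astype(float), pos.astype(float)


def for_curve(
    scores: np.ndarray, outcomes: np.ndarray, grid: CutoffGrid, *, group: str = ""
) -> CurveWithCI:
    """Raw false omission rate: events / rows among scores < c, with
    pointwise Wilson bounds; NaN where no row scores below c."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, int)
    if len(scores) == 0:
        raise ValueError("empty group")
    ev, n = _below_counts(scores, outcomes, grid)
    return proportion_curve(ev, n, grid, {"metric": "FOR", "group": group})


def fdr_curve(
    scores: np.ndarray, outcomes: np.ndarray, grid: CutoffGrid, *, group: str = ""
) -> CurveWithCI:
    """Raw false discovery rate: non-events / rows among scores >= c, with
    pointwise Wilson bounds; NaN where no row reaches c."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, int)
    if len(scores) == 0:
        raise ValueError("empty group")
    ev_below, n_below = _below_counts(scores, outcomes, grid)
    n_above = len(scores) - n_below
    ev_above = int(outcomes.sum()) - ev_below
    nonev_above = n_above - ev_above
    return proportion_curve(nonev_above, n_above, grid, {"metric": "FDR", "group": group})


def resolve_reference(
    table: CohortTable,
    rows: np.ndarray,
    request: RateCurveRequest,
    other_rows: np.ndarray | None = None,
) -> StrataDistribution:
    """Build the reference strata distribution named by the request."""
    if request.reference == "self":
        return strata_distribution(table, rows, request.age_bands, request.components)
    if other_rows is None:
        raise ValueError(f"reference {request.reference!r} needs the comparator rows")
    if request.reference == "other_group":
        return strata_distribution(
            table, other_rows, request.age_bands, request.components
        )
    return strata_distribution(
        table,
        np.asarray(rows, bool) | np.asarray(other_rows, bool),
        request.age_bands,
        request.components,
    )


def adjusted_rate_curve(
    table: CohortTable,
    rows: np.ndarray,
    request: RateCurveRequest,
    *,
    other_rows: np.ndarray | None = None,
    reference: StrataDistribution | None = None,
    rng: np.random.Generator | None = None,
    group: str = "",
) -> CurveWithCI:
    """Directly standardised FOR or FDR curve.

    estimate(c) = sum_s w_ref(s) * rate_s(c) over reference strata the
    group occupies; at each cutoff, strata whose conditioning set is empty
    are dropped and the remaining weights renormalised, with the dropped
    reference mass reported per cutoff in ``dropped_mass``. Pointwise 95%
    bounds come from a stratified bootstrap (percentile intervals),
    resampling individuals within each stratum.
    """
    if request.adjustment != "standardised":
        raise ValueError("request.adjustment must be 'standardised'")
    rows = np.asarray(rows, bool)
    if not rows.any():
        raise ValueError("empty group")
    rng = rng if rng is not None else np.random.default_rng()
    if reference is None:
        reference = resolve_reference(table, rows, request, other_rows)

    grid = request.grid
    k = len(grid)
    sub = table.df.loc[rows]
    keys = stratum_keys(sub, request.age_bands, request.components)
    reference, dropped_static = reference.restrict(keys.unique())
    if dropped_static > 1e-12:
        logger.warning(
            "standardisation dropped %.4f reference mass (strata empty in group)",
            dropped_static,
        )

    scores = sub["score"].to_numpy(float)
    outcomes = sub["outcome"].to_numpy(int)
    edges = np.concatenate(([0.0], grid.cutoffs, [1.0]))
    n_boot = request.n_boot
    # accumulated weighted rates and weights, per cutoff (point estimate)
    num = np.zeros(k)
    wsum = np.zeros(k)
    bnum = np.zeros((n_boot, k))
    bwsum = np.zeros((n_boot, k))
    is_for = request.metric == "FOR"

    for key, w in reference.weights.items():
        m = (keys == key).to_numpy()
        s, y = scores[m], outcomes[m]
        n_s = len(s)
        bin_idx = np.clip(np.digitize(s, edges) - 1, 0, k)
        # joint cell counts over (bin, outcome): cells 0..k are outcome 0,
        # cells k+1..2k+1 are outcome 1
        cell = bin_idx + (k + 1) * y
        counts = np.bincount(cell, minlength=2 * (k + 1)).astype(float)
        c0, c1 = counts[: k + 1], counts[k + 1 :]

        def rate_arrays(c0, c1):
            # cumulative counts strictly below each cutoff
            ev_below = np.cumsum(c1, axis=-1)[..., :k]
            all_below = ev_below + np.cumsum(c0, axis=-1)[..., :k]
            if is_for:
                denom = all_below
                numer = ev_below
            else:
                tot = (c0 + c1).sum(axis=-1, keepdims=True)
                tot_ev = c1.sum(axis=-1, keepdims=True)
                denom = tot - all_below
                numer = (tot - tot_ev) - (all_below - ev_below)
            ok = denom > 0
            rate = np.where(ok, np.divide(numer, np.where(ok, denom, 1.0)), 0.0)
            return rate, ok

        rate, ok = rate_arrays(c0, c1)
        num += w * rate
        wsum += w * ok

        reps = rng.multinomial(n_s, counts / n_s, size=n_boot).astype(float)
        brate, bok = rate_arrays(reps[:, : k + 1], reps[:, k + 1 :])
        bnum += w * brate
        bwsum += w * bok

    estimate = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), np.nan)
    boot = np.where(bwsum > 0, bnum / np.where(bwsum > 0, bwsum, 1.0), np.nan)
    lower = np.full(k, np.nan)
    upper = np.full(k, np.nan)
    any_rep = np.isfinite(boot).any(axis=0)
    if any_rep.any():
        with np.errstate(invalid="ignore"):
            lower[any_rep] = np.nanquantile(boot[:, any_rep], 0.025, axis=0)
            upper[any_rep] = np.nanquantile(boot[:, any_rep], 0.975, axis=0)
    lower[~np.isfinite(estimate)] = np.nan
    upper[~np.isfinite(estimate)] = np.nan

    # rows actually conditioning at each cutoff
    _, nb = _below_counts(scores, outcomes, grid)
    n_eff = nb if is_for else len(scores) - nb
    curve = CurveWithCI(
        grid, estimate, lower, upper, n_eff,
        {"metric": request.metric, "group": group, "adjusted": True,
         "reference": request.reference},
    )
    curve.dropped_mass = dropped_static + (1.0 - dropped_static) * (1.0 - wsum)
    return curve
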