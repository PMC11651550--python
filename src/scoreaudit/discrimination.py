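"""Group-wise discrimination (ROC / AUROC) and calibration curves.

AUROC is the probability that a randomly chosen individual who had the
event scores higher than one who did not, with half-credit for ties (the
standardised rank-sum statistic); ties are expected because deployed
scores have 1-99% display granularity. Its standard error uses the
placement-value (DeLong) variance estimator.

Calibration compares the mean predicted score with the observed event
rate within score bins: a well-calibrated score has observed ~= predicted
in every bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .curves import CurveWithCI, CutoffGrid, wilson_interval

logger = logging.getLogger(__name__)


class SingleClassError(ValueError):
    """Both outcome classes are required for ROC/AUROC."""


@dataclass
class RocResult:
    """ROC points on a cutoff grid plus the AUROC and its standard error."""

    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    auroc: float
    auroc_se: float
    n_events: int
    n_nonevents: int
    group: str = ""
    se_estimator: str = field(default="placement-value (DeLong)")


def _check_classes(outcomes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    outcomes = np.asarray(outcomes)
    pos = outcomes == 1
    neg = outcomes == 0
    if not pos.any() or not neg.any():
        raise SingleClassError("both outcome classes must be present")
    return pos, neg


def roc_points(
    scores: np.ndarray, outcomes: np.ndarray, grid: CutoffGrid, *, group: str = ""
) -> RocResult:
    """TPR = P(score >= c | event) and FPR = P(score >= c | no event) at
    each grid cutoff (positive prediction is score >= c)."""
    scores = np.asarray(scores, float)
    pos, neg = _check_classes(outcomes)
    sp = np.sort(scores[pos])
    sn = np.sort(scores[neg])
    # count of scores >= c via searchsorted on the sorted arrays
    tpr = 1.0 - np.searchsorted(sp, grid.cutoffs, side="left") / len(sp)
    fpr = 1.0 - np.searchsorted(sn, grid.cutoffs, side="left") / len(sn)
    est, se = auroc_with_se(scores, outcomes)
    return RocResult(
        fpr=fpr, tpr=tpr, cutoffs=grid.cutoffs, auroc=est, auroc_se=se,
        n_events=int(len(sp)), n_nonevents=int(len(sn)), group=group,
    )


def auroc_with_se(scores: np.ndarray, outcomes: np.ndarray) -> tuple[float, float]:
    """AUROC with half-credit ties and its placement-value standard error.

    The estimate equals (concordant + tied/2) / (n1 * n0), computed via
    midranks in O(n log n). The variance estimator is DeLong's:
    var = S10/n1 + S01/n0 with S10, S01 the sample variances of the
    event and non-event placement values.
    """
    scores = np.asarray(scores, float)
    pos, neg = _check_classes(outcomes)
    n1, n0 = int(pos.sum()), int(neg.sum())
    r_all = rankdata(scores)  # midranks over the pooled sample
    r_pos = rankdata(scores[pos])
    r_neg = rankdata(scores[neg])
    # placement values: V10[i] = fraction of non-events a given event beats
    v10 = (r_all[pos] - r_pos) / n0
    v01 = 1.0 - (r_all[neg] - r_neg) / n1
    est = float(v10.mean())
    if n1 > 1 and n0 > 1:
        var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    else:
        var = np.nan
    return est, float(np.sqrt(var))


def calibration_curve(
    scores: np.ndarray,
    outcomes: np.ndarray,
    *,
    n_bins: int = 20,
    min_count: int = 50,
    quantile_bins: bool = False,
    group: str = "",
) -> CurveWithCI:
    """Reliability curve: per score bin, the mean score (x) against the
    observed event rate (y) with pointwise 95% Wilson bounds.

    Default binning is 20 equal-width bins over (0, 1); set
    ``quantile_bins`` for equal-occupancy bins. Bins with fewer than
    ``min_count`` members are omitted and logged. The returned curve's
    grid holds the retained bins' mean scores; ``estimate`` is the event
    rate.
    """
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, int)
    if len(scores) == 0:
        raise ValueError("empty group")
    if quantile_bins:
        qs = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)))
        edges = qs
        edges[0], edges[-1] = 0.0, 1.0
    else:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    events = np.bincount(idx, weights=outcomes, minlength=len(edges) - 1)
    mean_score = np.full(len(counts), np.nan)
    nz = counts > 0
    mean_score[nz] = np.bincount(idx, weights=scores, minlength=len(counts))[nz] / counts[nz]

    keep = counts >= min_count
    n_dropped = int(np.count_nonzero(~keep & (counts > 0)))
    if n_dropped:
        logger.info(
            "calibration: omitted %d bin(s) with fewer than %d members",
            n_dropped, min_count,
        )
    if not keep.any():
        raise ValueError(f"all calibration bins below min_count={min_count}")
    x = mean_score[keep]
    order = np.argsort(x)
    x, ev, tot = x[order], events[keep][order], counts[keep][order].astype(float)
    rate = ev / tot
    lo, hi = wilson_interval(ev, tot)
    return CurveWithCI(
        CutoffGrid(np.clip(x, 1e-9, 1 - 1e-9)),
        rate, lo, hi, tot,
        {"metric": "calibration", "group": group,
         "binning": "quantile" if quantile_bins else "equal-width"},
    )
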