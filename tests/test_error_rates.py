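import numpy as np
import pytest
from hypothesis import given, settings

from scoreaudit import (
    CutoffGrid,
    RateCurveRequest,
    adjusted_rate_curve,
    fdr_curve,
    for_curve,
    validate_cohort,
)
from scoreaudit.strata import DEFAULT_AGE_BANDS

import oracles
from conftest import cohort_rows, make_frame

GRID = CutoffGrid.default()
SCORES = np.array([0.05, 0.2, 0.4, 0.15, 0.9, 0.7])
YS = np.array([0, 1, 0, 0, 1, 1])


def test_for_hand_example():
    curve = for_curve(SCORES, YS, CutoffGrid(np.array([0.5])))
    assert curve.estimate[0] == pytest.approx(0.25)  # 1 event of 4 below


def test_fdr_hand_example():
    curve = fdr_curve(SCORES, YS, CutoffGrid(np.array([0.5])))
    assert curve.estimate[0] == 0.0  # both rows >= 0.5 are events


def test_all_negative_outcomes():
    y0 = np.zeros(len(SCORES), int)
    f = for_curve(SCORES, y0, GRID)
    assert np.nanmax(f.estimate) == 0.0
    d = fdr_curve(SCORES, y0, GRID)
    assert np.nanmin(d.estimate) == 1.0


def test_empty_conditioning_sets_are_nan_not_zero():
    f = for_curve(SCORES, YS, CutoffGrid(np.array([0.01])))
    assert np.isnan(f.estimate[0]) and f.n_effective[0] == 0
    d = fdr_curve(SCORES, YS, CutoffGrid(np.array([0.95])))
    assert np.isnan(d.estimate[0]) and d.n_effective[0] == 0


def test_fdr_is_one_minus_precision_and_for_complement():
    rng = np.random.default_rng(0)
    scores = rng.uniform(0.011, 0.989, 400)
    ys = (rng.uniform(0, 1, 400) < scores).astype(int)
    f = for_curve(scores, ys, GRID)
    d = fdr_curve(scores, ys, GRID)
    for i, c in enumerate(GRID.cutoffs):
        above = scores >= c
        if above.any():
            precision = ys[above].mean()
            assert d.estimate[i] == pytest.approx(1 - precision, abs=1e-12)
        below = ~above
        if below.any():
            neg_rate = 1 - ys[below].mean()
            assert f.estimate[i] + neg_rate == pytest.approx(1.0, abs=1e-12)


def _two_strata_table():
    # stratum s1: FOR 0.25 below c=0.5; stratum s2: FOR 0.75
    s1 = {"age": 30, "sex": "M", "simd_decile": 4}
    s2 = {"age": 80, "sex": "F", "simd_decile": 1}
    rows = (
        [dict(s1, score=0.1, outcome=1)] + [dict(s1, score=0.1)] * 3
        + [dict(s2, score=0.1, outcome=1)] * 3 + [dict(s2, score=0.1)]
    )
    return validate_cohort(make_frame(rows))


def test_adjusted_hand_example_equal_weights():
    table = _two_strata_table()
    rows = np.ones(8, bool)
    req = RateCurveRequest(
        "FOR", CutoffGrid(np.array([0.5])), adjustment="standardised",
        reference="self", n_boot=20,
    )
    # self-reference here is uniform over the two strata (4 rows each)
    curve = adjusted_rate_curve(
        table, rows, req, rng=np.random.default_rng(0)
    )
    assert curve.estimate[0] == pytest.approx(0.5)


def test_self_standardisation_identity():
    """A group standardised to its own strata distribution reproduces the
    raw curve wherever both are defined."""
    rng = np.random.default_rng(1)
    n = 300
    rows = [
        {"age": int(a), "sex": s, "simd_decile": int(d),
         "score": round(x, 3), "outcome": int(y)}
        for a, s, d, x, y in zip(
            rng.integers(0, 100, n), rng.choice(["M", "F"], n),
            rng.integers(1, 11, n), rng.uniform(0.011, 0.989, n),
            rng.integers(0, 2, n),
        )
    ]
    table = validate_cohort(make_frame(rows))
    mask = np.ones(n, bool)
    raw = for_curve(table.df["score"].to_numpy(), table.df["outcome"].to_numpy(), GRID)
    req = RateCurveRequest("FOR", GRID, adjustment="standardised",
                           reference="self", n_boot=10)
    adj = adjusted_rate_curve(table, mask, req, rng=np.random.default_rng(2))
    both = np.isfinite(raw.estimate) & np.isfinite(adj.estimate)
    # identity holds at cutoffs where every occupied stratum conditions
    full = adj.dropped_mass < 1e-12
    assert np.allclose(adj.estimate[both & full], raw.estimate[both & full])


def test_reference_choices_differ_when_strata_differ():
    s1 = {"age": 30, "sex": "M", "simd_decile": 4}
    s2 = {"age": 80, "sex": "F", "simd_decile": 1}
    rows = (
        [dict(s1, score=0.1, outcome=1), dict(s1, score=0.1)] * 3
        + [dict(s2, score=0.1, outcome=1)] * 2
        + [dict(s1, score=0.1), dict(s2, score=0.1, outcome=1), dict(s2, score=0.1)]
    )
    table = validate_cohort(make_frame(rows))
    mask = np.arange(len(table)) < 8
    grid = CutoffGrid(np.array([0.5]))
    results = {}
    for ref in ("self", "other_group", "pooled_pair"):
        req = RateCurveRequest("FOR", grid, adjustment="standardised",
                               reference=ref, n_boot=10)
        results[ref] = adjusted_rate_curve(
            table, mask, req, other_rows=~mask, rng=np.random.default_rng(0)
        ).estimate[0]
    assert results["self"] != pytest.approx(results["other_group"])
    assert results["pooled_pair"] != pytest.approx(results["other_group"])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(rows=cohort_rows(min_rows=2, max_rows=20))
def test_rates_match_enumeration(rows):
    """for/fdr/adjusted curves equal explicit loops on small cohorts."""
    table = validate_cohort(make_frame(rows))
    scores = table.df["score"].to_numpy()
    ys = table.df["outcome"].to_numpy()
    f = for_curve(scores, ys, GRID)
    d = fdr_curve(scores, ys, GRID)
    recs = table.df.to_dict("records")
    for i, c in enumerate(GRID.cutoffs):
        ref = oracles.for_at(list(scores), list(ys), c)
        assert (np.isnan(f.estimate[i]) and ref is None) or (
            f.estimate[i] == pytest.approx(ref, abs=1e-12)
        )
        ref = oracles.fdr_at(list(scores), list(ys), c)
        assert (np.isnan(d.estimate[i]) and ref is None) or (
            d.estimate[i] == pytest.approx(ref, abs=1e-12)
        )
    # standardised to the group's own strata distribution
    req = RateCurveRequest("FOR", GRID, adjustment="standardised",
                           reference="self", n_boot=3)
    adj = adjusted_rate_curve(
        table, np.ones(len(rows), bool), req, rng=np.random.default_rng(0)
    )
    from collections import Counter

    keys = [oracles.stratum_key(r, list(DEFAULT_AGE_BANDS)) for r in recs]
    w = {k: v / len(recs) for k, v in Counter(keys).items()}
    for i, c in enumerate(GRID.cutoffs):
        ref = oracles.adjusted_rate_at(
            recs, c, "FOR", w, list(DEFAULT_AGE_BANDS), ("age", "sex", "simd")
        )
        assert (np.isnan(adj.estimate[i]) and ref is None) or (
            adj.estimate[i] == pytest.approx(ref, abs=1e-12)
        )
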