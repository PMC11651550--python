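import numpy as np
import pytest
from hypothesis import given, settings

from scoreaudit import (
    AdmissionTypeMap,
    classify_admission_type,
    decomposition_table,
    validate_cohort,
)

import oracles
from conftest import cohort_rows, make_frame


@pytest.mark.parametrize(
    "code, category",
    [
        ("S72.0", "external"),
        ("T30", "external"),
        ("V01", "external"),
        ("X60", "external"),
        ("Y10", "external"),
        ("R69", "abnormality-NEC"),
        ("J18.9", "respiratory"),
        ("j18.9", "respiratory"),  # case-insensitive
        ("I21", "circulatory"),
        ("O80", "obstetric"),
    ],
)
def test_letter_classification(code, category):
    assert classify_admission_type(code, AdmissionTypeMap()) == category


def test_uninterpretable_codes_route_to_unknown(caplog):
    tmap = AdmissionTypeMap()
    assert classify_admission_type("", tmap) == "unknown"
    assert classify_admission_type("123", tmap) == "unknown"


def test_map_must_cover_all_letters():
    with pytest.raises(ValueError, match="without a category"):
        AdmissionTypeMap({"A": "infectious"})


def test_map_file_roundtrip(tmp_path):
    tmap = AdmissionTypeMap()
    path = tmp_path / "map.csv"
    tmap.to_file(path)
    assert AdmissionTypeMap.from_file(path) == tmap


def _event_table(specs):
    """specs: list of (icd first letter, score)."""
    return validate_cohort(make_frame([
        {"score": s, "outcome": 1, "icd10_code": f"{l}00"} for l, s in specs
    ]))


def test_decomposition_hand_example():
    """Admissions typed [external x2, respiratory, digestive]; low-score
    subset is both externals: A=0.5, B=1.0, B-A=0.5."""
    table = _event_table([("S", 0.05), ("V", 0.05), ("J", 0.5), ("K", 0.5)])
    out = decomposition_table(
        table, np.ones(4, bool), rng=np.random.default_rng(0), n_boot=50
    )
    ext = out[out["category"] == "external"].iloc[0]
    assert ext["A"] == 0.5 and ext["B"] == 1.0 and ext["B_minus_A"] == 0.5


def test_no_low_score_events_flagged():
    table = _event_table([("S", 0.5), ("J", 0.6)])
    out = decomposition_table(
        table, np.ones(2, bool), threshold=0.02,
        rng=np.random.default_rng(0), n_boot=10,
    )
    assert not out["low_score_defined"].any()
    assert out["B"].isna().all() and out["B_minus_A"].isna().all()


def test_invalid_threshold_rejected():
    table = _event_table([("S", 0.5)])
    with pytest.raises(ValueError, match="threshold"):
        decomposition_table(table, np.ones(1, bool), threshold=0.0)


def test_group_without_events_rejected():
    table = validate_cohort(make_frame([{"score": 0.5}]))
    with pytest.raises(ValueError, match="no events"):
        decomposition_table(table, np.ones(1, bool))


def test_kinds_decomposed_separately():
    rows = [
        {"score": 0.05, "outcome": 1, "icd10_code": "S00"},
        {"score": 0.5, "outcome": 1, "icd10_code": "J00"},
        {"score": 0.05, "outcome": 1, "icd10_code": "I00",
         "event_kind": "death_without_admission"},
    ]
    out = decomposition_table(
        validate_cohort(make_frame(rows)), np.ones(3, bool),
        rng=np.random.default_rng(0), n_boot=10,
    )
    assert set(out["event_kind"]) == {"admission", "death_without_admission"}
    adm = out[out["event_kind"] == "admission"]
    assert adm["A"].sum() == pytest.approx(1.0)


def test_conservation_sums():
    rng = np.random.default_rng(4)
    letters = rng.choice(list("SJKIRC"), 200)
    scores = rng.uniform(0.011, 0.989, 200)
    table = _event_table(list(zip(letters, np.round(scores, 3))))
    out = decomposition_table(
        table, np.ones(200, bool), rng=np.random.default_rng(0), n_boot=20
    )
    for kind, sub in out.groupby("event_kind"):
        assert sub["A"].sum() == pytest.approx(1.0, abs=1e-12)
        assert sub["B"].sum() == pytest.approx(1.0, abs=1e-12)
        assert sub["B_minus_A"].sum() == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(rows=cohort_rows(min_rows=2, max_rows=20, with_events=True))
def test_decomposition_matches_enumeration(rows):
    """A and B equal explicit counting loops on small event sets."""
    table = validate_cohort(make_frame(rows))
    out = decomposition_table(
        table, np.ones(len(rows), bool), rng=np.random.default_rng(0), n_boot=3
    )
    tmap = AdmissionTypeMap()
    ev = table.df[table.df["outcome"] == 1]
    for kind, sub in out.groupby("event_kind"):
        evk = ev[ev["event_kind"] == kind]
        cats = [classify_admission_type(c, tmap) for c in evk["icd10_code"]]
        low = list(evk["score"] < 0.1)
        a_ref, b_ref = oracles.decomposition(cats, low)
        for _, row in sub.iterrows():
            assert row["A"] == pytest.approx(a_ref[row["category"]], abs=1e-12)
            if b_ref is not None:
                assert row["B"] == pytest.approx(
                    b_ref.get(row["category"], 0.0), abs=1e-12
                )
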