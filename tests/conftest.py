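import numpy as np
import pandas as pd
import pytest
from hypothesis import strategies as st

from scoreaudit import GeneratorConfig, generate_cohort, validate_cohort

LETTERS = list("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


def make_frame(rows: list[dict]) -> pd.DataFrame:
    base = {
        "id": None, "age": 40, "sex": "F", "simd_decile": 5,
        "ethnicity": "white", "urban_rural": "urban",
        "mainland_island": "mainland", "score": 0.2, "outcome": 0,
        "event_kind": "none", "icd10_code": "NA",
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(base, **row)
        if r["id"] is None:
            r["id"] = f"r{i}"
        if r["outcome"] == 1 and r["event_kind"] == "none":
            r["event_kind"] = "admission"
        if r["outcome"] == 1 and r["icd10_code"] == "NA":
            r["icd10_code"] = "J00"
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture
def tiny_table():
    """Six hand-written rows spanning both sexes, outcomes and strata."""
    return validate_cohort(make_frame([
        {"age": 70, "sex": "M", "simd_decile": 1, "score": 0.6, "outcome": 1,
         "icd10_code": "I21"},
        {"age": 70, "sex": "F", "simd_decile": 1, "score": 0.4, "outcome": 0},
        {"age": 30, "sex": "M", "simd_decile": 9, "score": 0.05, "outcome": 0},
        {"age": 20, "sex": "F", "simd_decile": 10, "score": 0.02, "outcome": 1,
         "icd10_code": "S72.0"},
        {"age": 45, "sex": "M", "simd_decile": 5, "score": 0.15, "outcome": 0,
         "ethnicity": "NA"},
        {"age": 85, "sex": "F", "simd_decile": 2, "score": 0.8, "outcome": 1,
         "event_kind": "death_without_admission", "icd10_code": "J18.9"},
    ]))


@pytest.fixture(scope="session")
def default_cohort_100k():
    """One large default-configuration cohort shared across slow tests."""
    return generate_cohort(GeneratorConfig(n=100_000, seed=12345))


# ---- hypothesis strategy for small random cohorts ----------------------

@st.composite
def cohort_rows(draw, min_rows=1, max_rows=20, with_events=False):
    n = draw(st.integers(min_rows, max_rows))
    rows = []
    n_events = 0
    for i in range(n):
        outcome = draw(st.integers(0, 1))
        n_events += outcome
        rows.append({
            "id": f"h{i}",
            "age": draw(st.integers(0, 100)),
            "sex": draw(st.sampled_from(["M", "F"])),
            "simd_decile": draw(st.integers(1, 10)),
            "ethnicity": draw(st.sampled_from(["white", "nonwhite", "NA"])),
            "score": round(draw(st.floats(0.01, 0.99)), 3),
            "outcome": outcome,
            "event_kind": "none" if outcome == 0 else draw(
                st.sampled_from(["admission", "death_without_admission"])
            ),
            "icd10_code": "NA" if outcome == 0 else (
                draw(st.sampled_from(LETTERS)) + "00"
            ),
        })
    if with_events and n_events == 0:
        rows[0].update(outcome=1, event_kind="admission", icd10_code="S00")
    return rows


@pytest.fixture
def small_table_factory():
    return lambda rows: validate_cohort(make_frame(rows))
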