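import io

import numpy as np
import pytest

from scoreaudit import (
    BUILTIN_SPECS,
    GeneratorConfig,
    generate_cohort,
    inject_group_miscalibration,
    write_cohort,
)
from scoreaudit.synthetic import ConfigError, _mixture_cells


def _dump(table):
    buf = io.StringIO()
    write_cohort(table, buf)
    return buf.getvalue()


def test_same_config_and_seed_is_byte_identical():
    cfg = GeneratorConfig(n=2000, seed=42)
    t1, _ = generate_cohort(cfg)
    t2, _ = generate_cohort(cfg)
    assert _dump(t1) == _dump(t2)


def test_different_seed_differs():
    t1, _ = generate_cohort(GeneratorConfig(n=2000, seed=1))
    t2, _ = generate_cohort(GeneratorConfig(n=2000, seed=2))
    assert _dump(t1) != _dump(t2)


def test_marginal_recovery(default_cohort_100k):
    """Each configured marginal is matched within 3 binomial SEs."""
    table, _ = default_cohort_100k
    cfg = GeneratorConfig()
    df = table.df
    n = len(df)

    def within(observed, p):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se, (observed, p)

    within((df["sex"] == "M").mean(), cfg.male_fraction)
    within(df["simd_decile"].isin((1, 2)).mean(), sum(cfg.simd_decile_weights[:2]))
    within(df["simd_decile"].isin((9, 10)).mean(), sum(cfg.simd_decile_weights[-2:]))
    within((df["ethnicity"] == "NA").mean(), cfg.ethnicity_missing_fraction)
    within(
        (df["ethnicity"] == "white").mean(),
        (1 - cfg.ethnicity_missing_fraction)
        * cfg.white_fraction / (cfg.white_fraction + cfg.nonwhite_fraction),
    )
    within((df["urban_rural"] == "urban").mean(), cfg.implied_urban_fraction())
    within((df["mainland_island"] == "island").mean(), cfg.implied_island_fraction())
    # age moments (mean within 3 SEs of the sample mean's SE)
    assert abs(df["age"].mean() - 43.3) < 3 * 23.8 / np.sqrt(n) + 0.15
    assert abs(df["age"].std() - 23.8) < 0.5


def test_score_equals_truth_without_noise_or_distortion():
    cfg = GeneratorConfig(n=500, seed=3, noise_sd=0.0)
    table, truth = generate_cohort(cfg)
    assert np.array_equal(table.df["score"].to_numpy(), truth.p)


def test_admission_type_mixture_recovery(default_cohort_100k):
    """Per-cell empirical first-letter frequencies match configured weights."""
    table, _ = default_cohort_100k
    cfg = GeneratorConfig()
    events = table.df[table.df["outcome"] == 1]
    cells = _mixture_cells(events)
    checked = 0
    for cell, weights in cfg.admission_mixture.items():
        sub = events[cells == cell]
        if len(sub) < 200:
            continue
        letters = sub["icd10_code"].str[0]
        for letter, w in weights.items():
            if w < 0.02:
                continue
            se = np.sqrt(w * (1 - w) / len(sub))
            assert abs((letters == letter).mean() - w) < 3.5 * se, (cell, letter)
            checked += 1
    assert checked > 20


def test_missing_ethnicity_rows_are_older(default_cohort_100k):
    table, _ = default_cohort_100k
    df = table.df
    assert (
        df.loc[df["ethnicity"] == "NA", "age"].mean()
        > df.loc[df["ethnicity"] != "NA", "age"].mean()
    )


@pytest.mark.parametrize(
    "bad, match",
    [
        ({"n": 0}, "n must be"),
        ({"male_fraction": 1.2}, "male_fraction"),
        ({"simd_decile_weights": [0.5, 0.5]}, "simd_decile_weights"),
        ({"white_fraction": 0.9}, "ethnicity fractions"),
        ({"noise_sd": -1.0}, "noise_sd"),
    ],
)
def test_invalid_config_fields_are_named(bad, match):
    with pytest.raises(ConfigError, match=match):
        generate_cohort(GeneratorConfig(**bad))


def test_config_yaml_roundtrip(tmp_path):
    cfg = GeneratorConfig(n=123, seed=9, noise_sd=0.5)
    path = tmp_path / "gen.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back == cfg


def test_inject_zero_shift_is_identity():
    table, _ = generate_cohort(GeneratorConfig(n=1000, seed=5))
    out = inject_group_miscalibration(table, BUILTIN_SPECS["sex"], "M", 0.0)
    assert np.array_equal(out.df["score"].to_numpy(), table.df["score"].to_numpy())


def test_inject_shift_leaves_other_group_untouched():
    table, _ = generate_cohort(GeneratorConfig(n=1000, seed=5))
    out = inject_group_miscalibration(table, BUILTIN_SPECS["sex"], "M", 1.0)
    f_mask = (table.df["sex"] == "F").to_numpy()
    m_mask = ~f_mask
    assert np.array_equal(
        out.df.loc[f_mask, "score"].to_numpy(),
        table.df.loc[f_mask, "score"].to_numpy(),
    )
    assert (
        out.df.loc[m_mask, "score"].to_numpy()
        > table.df.loc[m_mask, "score"].to_numpy()
    ).all()
    assert np.array_equal(out.df["outcome"], table.df["outcome"])


def test_unknown_injection_label_rejected():
    table, _ = generate_cohort(GeneratorConfig(n=100, seed=5))
    with pytest.raises(ValueError, match="unknown group label"):
        inject_group_miscalibration(table, BUILTIN_SPECS["sex"], "X", 1.0)
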