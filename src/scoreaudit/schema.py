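"""Cohort data schema, validation and delimited-text I/O.

One row per individual: demographics, an area-deprivation decile (SIMD,
1 = most deprived), a risk score held internally as a probability in the
open interval (0, 1) (the deployed 1-99 integer convention is treated as a
display convention only), the binary one-year outcome (emergency admission
or death), the event kind, and the ICD-10 primary-diagnosis code for rows
with an event.

Missing categorical values are encoded in files with the sentinel token
``"NA"``; in memory they are held as the same string so that round-trips
are exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel token for missing categorical values, both on disk and in memory.
NA_TOKEN = "NA"

#: Canonical column order of the cohort file.
COLUMNS = [
    "id",
    "age",
    "sex",
    "simd_decile",
    "ethnicity",
    "urban_rural",
    "mainland_island",
    "score",
    "outcome",
    "event_kind",
    "icd10_code",
]

CATEGORY_LEVELS = {
    "sex": {"M", "F"},
    "ethnicity": {"white", "nonwhite", NA_TOKEN},
    "urban_rural": {"urban", "rural", NA_TOKEN},
    "mainland_island": {"mainland", "island", NA_TOKEN},
    "event_kind": {"none", "admission", "death_without_admission"},
}

# Lowercase aliases accepted on read and normalised to canonical labels.
_ALIASES = {
    "sex": {"m": "M", "f": "F", "male": "M", "female": "F"},
    "ethnicity": {"w": "white", "nw": "nonwhite"},
    "urban_rural": {"u": "urban", "r": "rural"},
    "mainland_island": {"ml": "mainland", "il": "island"},
}


class CohortValidationError(ValueError):
    """Base class for all cohort-schema violations."""


class MissingColumnError(CohortValidationError):
    """A required column is absent from the file or frame."""


class ScoreRangeError(CohortValidationError):
    """A score lies outside the open interval (0, 1)."""


class CategoryError(CohortValidationError):
    """A categorical field holds a value outside its allowed levels."""


class FieldRangeError(CohortValidationError):
    """A numeric field (age, simd_decile, outcome) is out of range."""


class EventConsistencyError(CohortValidationError):
    """Outcome, event kind and ICD-10 code disagree."""


@dataclass
class CohortTable:
    """A validated cohort: wraps a :class:`pandas.DataFrame` with the
    canonical columns, in row order as read.

    Construct via :func:`validate_cohort`, :func:`read_cohort` or the
    synthetic generator rather than directly.
    """

    df: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(float)

    @property
    def outcomes(self) -> np.ndarray:
        return self.df["outcome"].to_numpy(int)


def _normalise_category(col: str, values: pd.Series) -> pd.Series:
    aliases = _ALIASES.get(col, {})
    out = values.astype(str).str.strip()
    lowered = out.str.lower()
    mapped = lowered.map(aliases)
    out = out.where(mapped.isna(), mapped)
    # blank cells and pandas' own missing markers become the sentinel
    out = out.replace({"": NA_TOKEN, "nan": NA_TOKEN, "<NA>": NA_TOKEN, "None": NA_TOKEN})
    return out


def validate_cohort(df: pd.DataFrame, *, require_icd10: bool = True) -> CohortTable:
    """Validate a raw frame against the cohort schema.

    Parameters
    ----------
    df
        Frame with at least the canonical columns (extra columns dropped).
    require_icd10
        When true (default), every row with ``outcome == 1`` must carry an
        ICD-10 code; disable for cohorts scored before event typing.

    Raises one of the named :class:`CohortValidationError` subclasses on
    the first violation, naming the row and field.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required column(s): {', '.join(missing)}")
    out = df[COLUMNS].copy().reset_index(drop=True)

    out["id"] = out["id"].astype(str)
    for col in ("age", "simd_decile", "outcome"):
        try:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FieldRangeError(f"column {col!r} is not integer-valued: {exc}") from None
    out["score"] = pd.to_numeric(out["score"], errors="coerce").astype(float)

    for col in CATEGORY_LEVELS:
        out[col] = _normalise_category(col, out[col])
        bad = ~out[col].isin(CATEGORY_LEVELS[col])
        if col in ("sex", "event_kind"):
            bad |= out[col] == NA_TOKEN
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CategoryError(
                f"row {row}: field {col!r} has invalid value {out.at[row, col]!r}"
            )

    score = out["score"].to_numpy()
    bad = ~(np.isfinite(score) & (score > 0.0) & (score < 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ScoreRangeError(
            f"row {row}: field 'score' = {score[row]!r} outside open interval (0, 1)"
        )
    if (out["age"] < 0).any():
        row = int(np.flatnonzero((out["age"] < 0).to_numpy())[0])
        raise FieldRangeError(f"row {row}: field 'age' negative")
    bad = ~out["simd_decile"].between(1, 10)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FieldRangeError(
            f"row {row}: field 'simd_decile' = {out.at[row, 'simd_decile']} outside 1-10"
        )
    if ~out["outcome"].isin((0, 1)).all():
        bad = ~out["outcome"].isin((0, 1))
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FieldRangeError(f"row {row}: field 'outcome' not in {{0, 1}}")

    out["icd10_code"] = out["icd10_code"].astype(str).str.strip()
    out["icd10_code"] = out["icd10_code"].replace(
        {"": NA_TOKEN, "nan": NA_TOKEN, "<NA>": NA_TOKEN, "None": NA_TOKEN}
    )
    outcome = out["outcome"].to_numpy()
    kind = out["event_kind"].to_numpy()
    code_absent = (out["icd10_code"] == NA_TOKEN).to_numpy()

    bad = (outcome == 0) & (kind != "none")
    bad |= (outcome == 1) & (kind == "none")
    bad |= (outcome == 0) & ~code_absent
    if require_icd10:
        bad |= (outcome == 1) & code_absent
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise EventConsistencyError(
            f"row {row}: outcome={outcome[row]}, event_kind={kind[row]!r}, "
            f"icd10_code={out.at[row, 'icd10_code']!r} are inconsistent "
            "(outcome=0 iff event_kind='none' iff code absent)"
        )
    return CohortTable(out)


def read_cohort(
    path, *, sep: str = ",", require_icd10: bool = True
) -> CohortTable:
    """Read and validate a delimited-text cohort file (UTF-8, header row)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return validate_cohort(df, require_icd10=require_icd10)


def write_cohort(table: CohortTable, path, *, sep: str = ",") -> None:
    """Write a cohort so that :func:`read_cohort` reproduces it exactly.

    Scores are written with full precision (repr round-trip).
    """
    df = table.df.copy()
    df["score"] = [repr(float(s)) for s in df["score"]]
    if isinstance(path, io.TextIOBase):
        df.to_csv(path, sep=sep, index=False)
    else:
        df.to_csv(path, sep=sep, index=False, encoding="utf-8")
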