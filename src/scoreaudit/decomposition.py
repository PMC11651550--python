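"""Decomposition of false negatives by admission type.

Within a group, events (emergency admissions, and deaths without a prior
admission, handled separately) are typed by the first letter of their
ICD-10 primary diagnosis — for deaths, the primary cause of death. For
each type the table reports its proportion among all the group's events
(A), its proportion among events whose score fell below the false-negative
threshold (B, default threshold 0.1), and the contrast B - A with a
bootstrap percentile interval. Types with B - A > 0 are disproportionately
poorly anticipated by the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from string import ascii_uppercase

import numpy as np
import pandas as pd

from .schema import CohortTable

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"

#: Default letter -> category assignment. External causes (S, T, V, X, Y:
#: accidents, self-harm, assault, complications) and abnormality-NEC (R,
#: symptoms/signs not elsewhere classified) follow the deployed grouping;
#: the remaining letters are grouped by ICD-10 chapter families.
DEFAULT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "infectious": ("A", "B"),
    "neoplasm": ("C",),
    "blood-immune": ("D",),
    "endocrine-metabolic": ("E",),
    "mental-behavioural": ("F",),
    "nervous": ("G",),
    "eye-ear": ("H",),
    "circulatory": ("I",),
    "respiratory": ("J",),
    "digestive": ("K",),
    "skin": ("L",),
    "musculoskeletal": ("M",),
    "genitourinary": ("N",),
    "obstetric": ("O",),
    "perinatal-congenital": ("P", "Q"),
    "abnormality-NEC": ("R",),
    "external": ("S", "T", "V", "X", "Y"),
    "other": ("U", "W", "Z"),
}


@dataclass(frozen=True)
class AdmissionTypeMap:
    """Mapping from ICD-10 first letter to a named admission category.

    Every letter A-Z must map to exactly one category; codes that are
    empty or start with a non-letter route to ``unknown`` with a warning.
    """

    letter_to_category: dict[str, str] = field(
        default_factory=lambda: {
            letter: cat
            for cat, letters in DEFAULT_CATEGORIES.items()
            for letter in letters
        }
    )

    def __post_init__(self):
        missing = set(ascii_uppercase) - set(self.letter_to_category)
        if missing:
            raise ValueError(f"letters without a category: {sorted(missing)}")

    @property
    def categories(self) -> list[str]:
        seen: list[str] = []
        for cat in self.letter_to_category.values():
            if cat not in seen:
                seen.append(cat)
        return seen

    @classmethod
    def from_file(cls, path, *, sep: str = ",") -> "AdmissionTypeMap":
        """Read a two-column (letter, category) delimited text file."""
        df = pd.read_csv(path, sep=sep, dtype=str)
        return cls(dict(zip(df.iloc[:, 0].str.upper(), df.iloc[:, 1])))

    def to_file(self, path, *, sep: str = ",") -> None:
        pd.DataFrame(
            sorted(self.letter_to_category.items()), columns=["letter", "category"]
        ).to_csv(path, sep=sep, index=False)


def classify_admission_type(code: str, type_map: AdmissionTypeMap) -> str:
    """Category of the uppercased first letter of an ICD-10 code."""
    code = (code or "").strip()
    if not code or code.upper() == "NA" or code[0].upper() not in ascii_uppercase:
        logger.warning("uninterpretable ICD-10 code %r routed to %r", code, UNKNOWN)
        return UNKNOWN
    return type_map.letter_to_category[code[0].upper()]


def decomposition_table(
    table: CohortTable,
    rows: np.ndarray,
    *,
    threshold: float = 0.1,
    type_map: AdmissionTypeMap | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    group: str = "",
) -> pd.DataFrame:
    """Per (event kind, category): A, B and B - A with a 95% interval.

    A = category's share of all the group's events of that kind; B = its
    share among events with score strictly below ``threshold``. The B - A
    interval comes from a nonparametric bootstrap over the group's events
    of that kind (percentile, respecting that the low-score events are a
    subset of all events). If no event scores below the threshold, B and
    B - A are NaN and flagged in the ``low_score_defined`` column.
    """
    rows = np.asarray(rows, bool)
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    type_map = type_map or AdmissionTypeMap()
    rng = rng if rng is not None else np.random.default_rng()

    sub = table.df.loc[rows]
    events = sub[sub["outcome"] == 1]
    if len(events) == 0:
        raise ValueError("group contains no events")

    frames = []
    for kind in ("admission", "death_without_admission"):
        ev = events[events["event_kind"] == kind]
        if len(ev) == 0:
            continue
        cats = np.array(
            [classify_admission_type(c, type_map) for c in ev["icd10_code"]]
        )
        low = (ev["score"].to_numpy(float) < threshold)
        frames.append(
            _decompose_kind(cats, low, type_map, kind, n_boot, rng, group)
        )
    out = pd.concat(frames, ignore_index=True)
    out["group"] = group
    return out


def _decompose_kind(
    cats: np.ndarray,
    low: np.ndarray,
    type_map: AdmissionTypeMap,
    kind: str,
    n_boot: int,
    rng: np.random.Generator,
    group: str,
) -> pd.DataFrame:
    categories = [c for c in type_map.categories if c in set(cats)]
    if UNKNOWN in set(cats):
        categories.append(UNKNOWN)
    cat_idx = {c: i for i, c in enumerate(categories)}
    idx = np.array([cat_idx[c] for c in cats])
    n_cat = len(categories)
    n_events = len(cats)
    n_low = int(low.sum())

    count_all = np.bincount(idx, minlength=n_cat).astype(float)
    count_low = np.bincount(idx[low], minlength=n_cat).astype(float)
    a = count_all / n_events
    if n_low > 0:
        b = count_low / n_low
        # joint cells (category, low?) so resampled B stays a subset of A
        cell = idx * 2 + low.astype(int)
        cell_counts = np.bincount(cell, minlength=2 * n_cat).astype(float)
        reps = rng.multinomial(n_events, cell_counts / n_events, size=n_boot).astype(float)
        rep_all = reps[:, 0::2] + reps[:, 1::2]
        rep_low = reps[:, 1::2]
        rep_nlow = rep_low.sum(axis=1, keepdims=True)
        rep_a = rep_all / n_events
        with np.errstate(invalid="ignore", divide="ignore"):
            rep_b = np.where(rep_nlow > 0, rep_low / rep_nlow, np.nan)
        diff = rep_b - rep_a
        lo = np.nanquantile(diff, 0.025, axis=0)
        hi = np.nanquantile(diff, 0.975, axis=0)
        b_minus_a = b - a
    else:
        logger.warning(
            "no %s events below threshold in group %r: B undefined", kind, group
        )
        b = np.full(n_cat, np.nan)
        b_minus_a = np.full(n_cat, np.nan)
        lo = np.full(n_cat, np.nan)
        hi = np.full(n_cat, np.nan)
    return pd.DataFrame(
        {
            "event_kind": kind,
            "category": categories,
            "count_all": count_all.astype(int),
            "count_low_score": count_low.astype(int),
            "A": a,
            "B": b,
            "B_minus_A": b_minus_a,
            "lower": lo,
            "upper": hi,
            "low_score_defined": n_low > 0,
        }
    )
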