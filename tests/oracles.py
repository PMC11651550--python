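"""Independent brute-force reference implementations.

Everything here is written as explicit loops over individuals, pairs and
strata, deliberately ignoring the package's vectorised code paths, so it
can serve as an enumeration oracle on small cohorts.
"""

from bisect import bisect_right
from collections import Counter


def stratum_key(row, age_bands, components=("age", "sex", "simd")):
    parts = []
    if "age" in components:
        idx = bisect_right(list(age_bands), row["age"]) - 1
        parts.append(min(max(idx, 0), len(age_bands) - 1))
    if "sex" in components:
        parts.append(row["sex"])
    if "simd" in components:
        parts.append(row["simd_decile"])
    return tuple(parts)


def cdf_at(scores, c):
    return sum(1 for s in scores if s < c) / len(scores)


def counterfactual_at(rows_target, rows_source, c, age_bands, components):
    weights = Counter(stratum_key(r, age_bands, components) for r in rows_target)
    total = sum(weights.values())
    by_stratum = {}
    for r in rows_source:
        by_stratum.setdefault(stratum_key(r, age_bands, components), []).append(
            r["score"]
        )
    kept = {s: w for s, w in weights.items() if s in by_stratum}
    norm = sum(kept.values())
    if norm == 0:
        raise ValueError("no common stratum")
    return sum(
        (w / norm) * cdf_at(by_stratum[s], c) for s, w in kept.items()
    )


def auroc(scores, outcomes):
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    neg = [s for s, y in zip(scores, outcomes) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def for_at(scores, outcomes, c):
    below = [(s, y) for s, y in zip(scores, outcomes) if s < c]
    if not below:
        return None
    return sum(y for _, y in below) / len(below)


def fdr_at(scores, outcomes, c):
    above = [(s, y) for s, y in zip(scores, outcomes) if s >= c]
    if not above:
        return None
    return sum(1 - y for _, y in above) / len(above)


def adjusted_rate_at(rows, c, metric, ref_weights, age_bands, components):
    """Directly standardised FOR/FDR at one cutoff; rows are the group's
    rows, ref_weights a dict stratum -> weight (restricted to occupied
    strata and renormalised by the caller's convention)."""
    occupied = {}
    for r in rows:
        occupied.setdefault(stratum_key(r, age_bands, components), []).append(r)
    kept = {s: w for s, w in ref_weights.items() if s in occupied}
    norm0 = sum(kept.values())
    num = 0.0
    wsum = 0.0
    for s, w in kept.items():
        scores = [r["score"] for r in occupied[s]]
        ys = [r["outcome"] for r in occupied[s]]
        rate = for_at(scores, ys, c) if metric == "FOR" else fdr_at(scores, ys, c)
        if rate is None:
            continue
        num += (w / norm0) * rate
        wsum += w / norm0
    if wsum == 0:
        return None
    return num / wsum


def decomposition(categories, low_mask):
    n = len(categories)
    n_low = sum(low_mask)
    cats = sorted(set(categories))
    a = {c: sum(1 for x in categories if x == c) / n for c in cats}
    b = (
        {
            c: sum(1 for x, l in zip(categories, low_mask) if l and x == c) / n_low
            for c in cats
        }
        if n_low
        else None
    )
    return a, b
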