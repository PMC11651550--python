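"""Cutoff grids and metric curves with pointwise confidence intervals.

A curve is any metric evaluated on an ordered grid of score cutoffs in
(0, 1), with pointwise 95% interval bounds. Estimates may be undefined at
some cutoffs (e.g. a false-omission rate where nobody scores below the
cutoff); undefined values are carried as NaN end-to-end, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class CutoffGrid:
    """Strictly increasing cutoffs in the open interval (0, 1).

    The default grid is 0.01, 0.02, ..., 0.99, mirroring the 1-99%
    display convention of the deployed score.
    """

    cutoffs: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cutoffs, float)
        if c.ndim != 1 or len(c) == 0:
            raise ValueError("grid must be a non-empty 1-d array")
        if not (np.all(np.diff(c) > 0) and c[0] > 0.0 and c[-1] < 1.0):
            raise ValueError("cutoffs must be strictly increasing within (0, 1)")
        object.__setattr__(self, "cutoffs", c)

    def __len__(self) -> int:
        return len(self.cutoffs)

    @classmethod
    def default(cls) -> "CutoffGrid":
        return cls(np.round(np.arange(1, 100) / 100.0, 2))


@dataclass
class CurveWithCI:
    """A metric on a cutoff grid with pointwise 95% bounds.

    ``estimate``, ``lower`` and ``upper`` are NaN where undefined;
    ``n_effective`` is the size of the conditioning set at each cutoff.
    ``metadata`` records the metric name, group, and adjustment details.
    """

    grid: CutoffGrid
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_effective: np.ndarray
    metadata: dict = field(default_factory=dict)
    #: per-cutoff reference-distribution mass dropped by empty strata
    #: (standardised curves only; zeros otherwise)
    dropped_mass: np.ndarray | None = None

    def __post_init__(self):
        k = len(self.grid)
        for name in ("estimate", "lower", "upper", "n_effective"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have shape ({k},)")
            setattr(self, name, arr)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.estimate)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cutoff": self.grid.cutoffs,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
                "n_effective": self.n_effective,
            }
        )
        if self.dropped_mass is not None:
            df["dropped_mass"] = self.dropped_mass
        for key in ("metric", "group", "adjusted", "reference", "se_estimator"):
            if key in self.metadata:
                df[key] = self.metadata[key]
        return df

    def write(self, path, *, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False, float_format="%.10g")


def wilson_interval(
    successes: np.ndarray, totals: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Wilson score interval; NaN where the total is zero."""
    successes = np.asarray(successes, float)
    totals = np.asarray(totals, float)
    lower = np.full(successes.shape, np.nan)
    upper = np.full(successes.shape, np.nan)
    ok = totals > 0
    if ok.any():
        lo, hi = proportion_confint(
            successes[ok], totals[ok], alpha=alpha, method="wilson"
        )
        lower[ok] = lo
        upper[ok] = hi
    return lower, upper


def proportion_curve(
    successes: np.ndarray,
    totals: np.ndarray,
    grid: CutoffGrid,
    metadata: dict | None = None,
) -> CurveWithCI:
    """Assemble a proportion-valued curve with Wilson bounds; undefined
    (NaN) wherever the conditioning set is empty."""
    successes = np.asarray(successes, float)
    totals = np.asarray(totals, float)
    est = np.full(successes.shape, np.nan)
    ok = totals > 0
    est[ok] = successes[ok] / totals[ok]
    lower, upper = wilson_interval(successes, totals)
    return CurveWithCI(grid, est, lower, upper, totals, dict(metadata or {}))


def curve_difference(a: CurveWithCI, b: CurveWithCI) -> CurveWithCI:
    """Pointwise difference a - b between two curves on the same grid.

    Interval half-widths combine by independent-groups variance addition:
    treating each input's interval half-width as z * SE, the difference's
    half-width is the root-sum-of-squares of the inputs'. This applies
    uniformly whether the inputs carry Wilson or bootstrap-percentile
    bounds (both are symmetrised here).
    """
    if not np.array_equal(a.grid.cutoffs, b.grid.cutoffs):
        raise ValueError("curves are on different cutoff grids")
    est = a.estimate - b.estimate
    half_a = (a.upper - a.lower) / 2.0
    half_b = (b.upper - b.lower) / 2.0
    half = np.sqrt(half_a**2 + half_b**2)
    meta = {
        "metric": f"{a.metadata.get('metric', '?')}-difference",
        "group": f"{a.metadata.get('group', 'a')}-{b.metadata.get('group', 'b')}",
    }
    for key in ("adjusted", "reference"):
        if key in a.metadata:
            meta[key] = a.metadata[key]
    n_eff = np.fmin(a.n_effective, b.n_effective)
    return CurveWithCI(a.grid, est, est - half, est + half, n_eff, meta)


def read_curve(path, *, sep: str = ",") -> CurveWithCI:
    """Read a curve previously serialised with :meth:`CurveWithCI.write`."""
    df = pd.read_csv(path, sep=sep)
    meta = {
        key: df[key].iloc[0]
        for key in ("metric", "group", "adjusted", "reference", "se_estimator")
        if key in df.columns
    }
    curve = CurveWithCI(
        CutoffGrid(df["cutoff"].to_numpy()),
        df["estimate"].to_numpy(),
        df["lower"].to_numpy(),
        df["upper"].to_numpy(),
        df["n_effective"].to_numpy(),
        meta,
    )
    if "dropped_mass" in df.columns:
        curve.dropped_mass = df["dropped_mass"].to_numpy()
    return curve
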