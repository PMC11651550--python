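"""Synthetic scored-cohort generator with known ground truth.

Emulates the statistical structure a demographic audit of an
emergency-admission risk score assumes, without any real records:

* demographic marginals matching a national primary-care population
  (male fraction, age mixture, deprivation-decile weights, ethnicity with
  age-dependent non-random missingness, urban/rural depending on
  deprivation, island residence concentrated in rural postcodes);
* a logistic true-risk model in age, sex and deprivation, plus optional
  direct group effects and individual log-odds noise;
* a reported score equal to the true risk, optionally distorted per group
  on the log-odds scale (shift/scale) to emulate miscalibration;
* events split into emergency admissions and deaths-without-admission
  (probability rising with age), each typed with an ICD-10 code whose
  first letter is drawn from a per-(age band, sex, deprivation) mixture.

The generator's role is structural realism plus known ground truth, not
fidelity to any deployed model. All draws flow from one seeded generator,
so cohorts are byte-identical given the same config and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .groups import GroupSpec, assign_group
from .schema import NA_TOKEN, CohortTable, validate_cohort

#: Age standardisation constants of the risk model (population mean/SD).
AGE_CENTER, AGE_SCALE = 43.3, 23.8

_LETTERS = list("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


class ConfigError(ValueError):
    """A generator-config field is invalid (named in the message)."""


def _default_age_mixture() -> list[tuple[float, float, float]]:
    # (mean, sd, weight) of truncated-normal components on [0, 110];
    # tuned so the mixture has mean 43.3, SD 23.8
    return [(5.87, 7.5, 0.20), (45.0, 13.0, 0.6317), (78.0, 7.5, 0.1683)]


def _default_simd_weights() -> list[float]:
    # top two deciles sum to 0.215 (most-deprived quintile), bottom two to
    # 0.187 (least-deprived), remainder spread over the middle six
    w = [0.1075, 0.1075] + [0.0997] * 6 + [0.0935, 0.0935]
    total = sum(w)
    return [x / total for x in w]


def _default_urban_by_decile() -> list[float]:
    # deprived areas are predominantly urban; mid deciles less so, chosen
    # so the implied overall urban fraction is ~0.833
    return [0.965, 0.95, 0.85, 0.80, 0.76, 0.74, 0.74, 0.76, 0.85, 0.919]


def _default_admission_mixture() -> dict[str, dict[str, float]]:
    """Per-cell ICD-10 first-letter weights, cells keyed "ageband|sex|dep".

    Age bands: young (<25), adult (25-64), elderly (65+); deprivation:
    most (deciles 1-2), mid, least (9-10). External-cause letters
    (S, T, V, X, Y) are inflated in young males; circulatory/respiratory
    in the elderly; obstetric codes only for adult females.
    """
    base = {
        "A": 0.040, "B": 0.010, "C": 0.030, "D": 0.010, "E": 0.030,
        "F": 0.030, "G": 0.020, "H": 0.010, "I": 0.100, "J": 0.140,
        "K": 0.130, "L": 0.020, "M": 0.040, "N": 0.050, "O": 0.000,
        "P": 0.005, "Q": 0.005, "R": 0.160, "S": 0.080, "T": 0.030,
        "V": 0.020, "X": 0.020, "Y": 0.020, "U": 0.000, "W": 0.000,
        "Z": 0.000,
    }
    external = set("STVXY")
    cells: dict[str, dict[str, float]] = {}
    for band in ("young", "adult", "elderly"):
        for sex in ("M", "F"):
            for dep in ("most", "mid", "least"):
                w = dict(base)
                if band == "young":
                    for ltr in external:
                        w[ltr] *= 2.5 if sex == "M" else 1.6
                    w["I"] *= 0.3
                    w["C"] *= 0.3
                if band == "elderly":
                    w["I"] *= 1.8
                    w["J"] *= 1.4
                    w["C"] *= 1.5
                    for ltr in external:
                        w[ltr] *= 0.6
                if band == "adult" and sex == "F":
                    w["O"] = 0.08
                if dep == "most":
                    for ltr in external:
                        w[ltr] *= 1.3
                total = sum(w.values())
                cells[f"{band}|{sex}|{dep}"] = {
                    k: v / total for k, v in w.items() if v > 0
                }
    return cells


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with defaults reproducing the
    target population's whole-cohort marginals."""

    n: int = 100_000
    seed: int = 0

    # demographic marginals
    male_fraction: float = 0.454
    age_mixture: list = field(default_factory=_default_age_mixture)
    simd_decile_weights: list = field(default_factory=_default_simd_weights)
    white_fraction: float = 0.668
    nonwhite_fraction: float = 0.218
    ethnicity_missing_fraction: float = 0.114
    #: log-odds of missing ethnicity per SD of age (non-random missingness:
    #: older individuals are more often missing)
    ethnicity_missing_age_slope: float = 0.5
    urban_by_decile: list = field(default_factory=_default_urban_by_decile)
    #: log-odds of urban residence per SD of age-band midpoint (5-year
    #: bands; 0 = no age dependence). Band-level rather than exact-age
    #: dependence, so that age-mediated residence effects live exactly on
    #: the strata grid the audit standardises over.
    urban_age_slope: float = 0.0
    urban_missing_fraction: float = 0.0007
    island_given_rural: float = 0.083
    island_given_urban: float = 0.0058
    island_missing_fraction: float = 0.0005

    # true-risk model (log-odds scale)
    risk_intercept: float = -3.2
    risk_beta_age: float = 1.5
    risk_beta_male: float = 0.10
    #: coefficient on the deprivation score (5.5 - decile)/4.5, which is
    #: +1 at the most-deprived and -1 at the least-deprived extreme
    risk_beta_deprivation: float = 0.35
    #: direct group effects, keyed "column:value" (e.g. "urban_rural:rural")
    risk_group_effects: dict = field(default_factory=dict)
    noise_sd: float = 0.8

    #: per-group score distortion, keyed "column:value" -> [shift, scale]
    #: applied as logit(score) = scale * logit(p) + shift
    calibration_distortion: dict = field(default_factory=dict)

    # event-kind model: P(death without admission | event) =
    # death_max * sigmoid((age - death_age_midpoint) / death_age_scale)
    death_age_midpoint: float = 80.0
    death_age_scale: float = 8.0
    death_max: float = 0.6

    #: per-cell ICD-10 first-letter weights, cells "ageband|sex|dep"
    admission_mixture: dict = field(default_factory=_default_admission_mixture)

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigError("n must be a positive integer")
        fracs = {
            "male_fraction": self.male_fraction,
            "white_fraction": self.white_fraction,
            "nonwhite_fraction": self.nonwhite_fraction,
            "ethnicity_missing_fraction": self.ethnicity_missing_fraction,
            "urban_missing_fraction": self.urban_missing_fraction,
            "island_given_rural": self.island_given_rural,
            "island_given_urban": self.island_given_urban,
            "island_missing_fraction": self.island_missing_fraction,
            "death_max": self.death_max,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if len(self.simd_decile_weights) != 10 or not np.isclose(
            sum(self.simd_decile_weights), 1.0
        ):
            raise ConfigError("simd_decile_weights must be 10 weights summing to 1")
        if len(self.urban_by_decile) != 10:
            raise ConfigError("urban_by_decile must give 10 probabilities")
        if not np.isclose(
            self.white_fraction + self.nonwhite_fraction
            + self.ethnicity_missing_fraction, 1.0, atol=1e-6,
        ):
            raise ConfigError("ethnicity fractions must sum to 1")
        for cell, weights in self.admission_mixture.items():
            if not np.isclose(sum(weights.values()), 1.0):
                raise ConfigError(f"admission_mixture[{cell!r}] weights must sum to 1")
            bad = [k for k in weights if k not in _LETTERS]
            if bad:
                raise ConfigError(f"admission_mixture[{cell!r}] has non-letters {bad}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    # -- file round-trip ------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        # YAML lists of lists -> tuples for mixture components
        cfg.age_mixture = [tuple(c) for c in cfg.age_mixture]
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["age_mixture"] = [list(c) for c in self.age_mixture]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    # -- implied marginals (analytic, for tests and documentation) ------
    def implied_urban_fraction(self) -> float:
        """Overall urban fraction implied by the per-decile probabilities
        (at zero age slope), net of the missing fraction."""
        w = np.asarray(self.simd_decile_weights)
        u = np.asarray(self.urban_by_decile)
        return float((w * u).sum() * (1 - self.urban_missing_fraction))

    def implied_island_fraction(self) -> float:
        urban = self.implied_urban_fraction()
        rural = (1 - self.urban_missing_fraction) - urban
        p = urban * self.island_given_urban + rural * self.island_given_rural
        return float(p * (1 - self.island_missing_fraction))


@dataclass
class LatentTruth:
    """Ground truth underlying a generated cohort: the true event
    probability per individual and the linear predictor it came from."""

    p: np.ndarray
    linear_predictor: np.ndarray


def _sample_ages(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    comps = cfg.age_mixture
    w = np.array([c[2] for c in comps], float)
    w = w / w.sum()
    idx = rng.choice(len(comps), size=cfg.n, p=w)
    mu = np.array([c[0] for c in comps])[idx]
    sd = np.array([c[1] for c in comps])[idx]
    age = rng.normal(mu, sd)
    bad = (age < 0) | (age > 110)
    while bad.any():  # rejection keeps each component's truncated shape
        age[bad] = rng.normal(mu[bad], sd[bad])
        bad = (age < 0) | (age > 110)
    return np.round(age).astype(np.int64)


def _calibrated_intercept(z: np.ndarray, slope: float, target: float) -> float:
    """Intercept a such that mean(sigmoid(a + slope * z)) equals the
    target fraction on this sample."""
    if target <= 0.0:
        return -np.inf
    f = lambda a: expit(a + slope * z).mean() - target
    return brentq(f, -30.0, 30.0)


def _group_key_mask(df: pd.DataFrame, key: str) -> np.ndarray:
    col, _, value = key.partition(":")
    if col not in df.columns:
        raise ConfigError(f"unknown column in group key {key!r}")
    if col in ("age", "simd_decile", "outcome"):
        raise ConfigError(f"group key {key!r} must name a categorical column")
    return (df[col] == value).to_numpy()


def _mixture_cells(df: pd.DataFrame) -> pd.Series:
    band = pd.cut(
        df["age"], [-1, 24, 64, 200], labels=["young", "adult", "elderly"]
    ).astype(str)
    dep = pd.cut(
        df["simd_decile"], [0, 2, 8, 10], labels=["most", "mid", "least"]
    ).astype(str)
    return band + "|" + df["sex"] + "|" + dep


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[CohortTable, LatentTruth]:
    """Draw a full synthetic scored cohort. Deterministic given
    (config, seed); ``seed`` overrides ``config.seed`` when given."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    age = _sample_ages(config, rng)
    z = (age - AGE_CENTER) / AGE_SCALE
    simd = rng.choice(
        np.arange(1, 11), size=n, p=np.asarray(config.simd_decile_weights)
    )

    # ethnicity: age-dependent missingness, then white/nonwhite split
    a0 = _calibrated_intercept(
        z, config.ethnicity_missing_age_slope, config.ethnicity_missing_fraction
    )
    p_miss = expit(a0 + config.ethnicity_missing_age_slope * z) if np.isfinite(a0) else np.zeros(n)
    eth_missing = rng.random(n) < p_miss
    denom = config.white_fraction + config.nonwhite_fraction
    white = rng.random(n) < (config.white_fraction / denom)
    ethnicity = np.where(eth_missing, NA_TOKEN, np.where(white, "white", "nonwhite"))

    # urban/rural: deprivation- (and optionally age-band-) dependent
    p_urban_base = np.asarray(config.urban_by_decile)[simd - 1]
    band_mid = (np.minimum(age // 5, 18) * 5 + 2.5 - AGE_CENTER) / AGE_SCALE
    lo = logit(np.clip(p_urban_base, 1e-9, 1 - 1e-9)) + config.urban_age_slope * band_mid
    urban = rng.random(n) < expit(lo)
    ur_missing = rng.random(n) < config.urban_missing_fraction
    urban_rural = np.where(ur_missing, NA_TOKEN, np.where(urban, "urban", "rural"))

    p_island = np.where(urban, config.island_given_urban, config.island_given_rural)
    island = rng.random(n) < p_island
    isl_missing = rng.random(n) < config.island_missing_fraction
    mainland_island = np.where(
        isl_missing, NA_TOKEN, np.where(island, "island", "mainland")
    )

    df = pd.DataFrame(
        {
            "id": [f"P{i:07d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "simd_decile": simd,
            "ethnicity": ethnicity,
            "urban_rural": urban_rural,
            "mainland_island": mainland_island,
        }
    )

    dep_score = (5.5 - simd) / 4.5
    lp = (
        config.risk_intercept
        + config.risk_beta_age * z
        + config.risk_beta_male * (sex == "M")
        + config.risk_beta_deprivation * dep_score
    )
    for key, eff in config.risk_group_effects.items():
        lp = lp + float(eff) * _group_key_mask(df, key)
    if config.noise_sd > 0:
        lp = lp + rng.normal(0.0, config.noise_sd, n)
    p = np.clip(expit(lp), 0.01, 0.99)
    outcome = (rng.random(n) < p).astype(np.int64)

    score = p.copy()  # undistorted rows report the true risk exactly
    for key, (shift, scale) in config.calibration_distortion.items():
        mask = _group_key_mask(df, key)
        distorted = expit(float(scale) * logit(p[mask]) + float(shift))
        score[mask] = np.clip(distorted, 0.01, 0.99)

    # event kind and ICD-10 typing
    p_death = config.death_max * expit(
        (age - config.death_age_midpoint) / config.death_age_scale
    )
    death = (rng.random(n) < p_death) & (outcome == 1)
    event_kind = np.where(
        outcome == 1, np.where(death, "death_without_admission", "admission"), "none"
    )

    df["score"] = score
    df["outcome"] = outcome
    df["event_kind"] = event_kind
    icd = np.full(n, NA_TOKEN, dtype=object)
    cells = _mixture_cells(df)
    ev_idx = np.flatnonzero(outcome == 1)
    for cell, weights in config.admission_mixture.items():
        members = ev_idx[cells.iloc[ev_idx].to_numpy() == cell]
        if len(members) == 0:
            continue
        letters = list(weights)
        w = np.array([weights[l] for l in letters], float)
        drawn = rng.choice(len(letters), size=len(members), p=w / w.sum())
        icd[members] = [letters[j] + "00" for j in drawn]
    missing_cells = set(cells.iloc[ev_idx]) - set(config.admission_mixture)
    if missing_cells:
        raise ConfigError(f"admission_mixture lacks cell(s) {sorted(missing_cells)}")
    df["icd10_code"] = icd

    return validate_cohort(df), LatentTruth(p=p, linear_predictor=np.asarray(lp))


def inject_group_miscalibration(
    table: CohortTable, spec: GroupSpec, label: str, shift: float
) -> CohortTable:
    """Shift the reported scores of one group on the log-odds scale,
    leaving outcomes (and every other group's scores) untouched."""
    if label not in (spec.label_a, spec.label_b):
        raise ValueError(f"unknown group label {label!r} for {spec!r}")
    labels = assign_group(table, spec)
    df = table.df.copy()
    if shift == 0.0:
        return CohortTable(df)
    mask = (labels == label).to_numpy()
    s = df.loc[mask, "score"].to_numpy(float)
    df.loc[mask, "score"] = np.clip(expit(logit(s) + shift), 0.005, 0.995)
    return validate_cohort(df, require_icd10=False)
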