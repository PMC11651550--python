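"""Orchestration: the full audit (six comparisons x all metrics) from one
config, with per-stage seeding, stage isolation and a file-based bundle.

Every stochastic stage draws from a generator seeded deterministically
from the root seed and the (comparison, metric) position, so re-running
the same config and seed reproduces every output byte-for-byte. A failure
in one (comparison, metric) stage is recorded in the manifest and the
remaining stages still run.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import CutoffGrid, curve_difference
from .decomposition import AdmissionTypeMap, decomposition_table
from .discrimination import calibration_curve, roc_points
from .error_rates import (
    RateCurveRequest, adjusted_rate_curve, fdr_curve, for_curve,
)
from .groups import BUILTIN_SPECS, GroupSpec, group_masks
from .parity import counterfactual_cdf, score_cdf
from .schema import CohortTable, read_cohort
from .strata import ALL_COMPONENTS, DEFAULT_AGE_BANDS
from .summary import summarize_cohort
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


class AuditConfigError(ValueError):
    """The audit config references something that does not exist."""


@dataclass
class AuditConfig:
    """One run of the audit: input, comparisons, grids, seeds, output."""

    out_dir: str
    cohort_path: str | None = None
    generator: dict | None = None  # GeneratorConfig fields for synthetic runs
    comparisons: list = field(default_factory=lambda: list(BUILTIN_SPECS))
    cutoffs: list | None = None  # default 0.01..0.99
    age_bands: list | None = None  # default 5-year bands
    calibration_bins: int = 20
    calibration_min_count: int = 50
    n_boot: int = 1000
    seed: int = 0
    fn_threshold: float = 0.1
    reference: str = "pooled_pair"

    @classmethod
    def from_yaml(cls, path) -> "AuditConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise AuditConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def resolve_specs(self) -> list[GroupSpec]:
        specs = []
        for name in self.comparisons:
            if name not in BUILTIN_SPECS:
                raise AuditConfigError(
                    f"unknown group variable {name!r}; known: {sorted(BUILTIN_SPECS)}"
                )
            specs.append(BUILTIN_SPECS[name])
        return specs

    def resolve_grid(self) -> CutoffGrid:
        if self.cutoffs is None:
            return CutoffGrid.default()
        return CutoffGrid(np.asarray(self.cutoffs, float))

    def resolve_age_bands(self) -> np.ndarray:
        if self.age_bands is None:
            return DEFAULT_AGE_BANDS
        return np.asarray(self.age_bands, float)


@dataclass
class ReportBundle:
    """Where the audit wrote its outputs, plus the run manifest."""

    out_dir: Path
    manifest: dict

    @property
    def files(self) -> list[Path]:
        return sorted(
            p.relative_to(self.out_dir)
            for p in self.out_dir.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        )


def _stage_rng(root_seed: int, comp_idx: int, metric_idx: int) -> np.random.Generator:
    """One generator per (comparison, metric), derived deterministically."""
    return np.random.default_rng(
        np.random.SeedSequence((int(root_seed), comp_idx, metric_idx))
    )


def run_audit(config: AuditConfig) -> ReportBundle:
    """Run every comparison x metric stage and write the bundle."""
    specs = config.resolve_specs()  # validate before any computation
    grid = config.resolve_grid()
    age_bands = config.resolve_age_bands()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    caught: list[str] = []
    errors: list[str] = []
    handler = _ListHandler(caught)
    logging.getLogger("scoreaudit").addHandler(handler)
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            table = _load_cohort(config)
            _run_stages(
                config, table, specs, grid, age_bands, out, caught, errors
            )
            caught.extend(str(w.message) for w in wlist)
    finally:
        logging.getLogger("scoreaudit").removeHandler(handler)

    manifest = {
        "software": {"name": "scoreaudit", "version": __version__},
        "seed": config.seed,
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "warnings": caught,
        "errors": errors,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    return ReportBundle(out_dir=out, manifest=manifest)


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(record.getMessage())


def _load_cohort(config: AuditConfig) -> CohortTable:
    if (config.cohort_path is None) == (config.generator is None):
        raise AuditConfigError("exactly one of cohort_path / generator is required")
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    gen = GeneratorConfig(**config.generator)
    table, _ = generate_cohort(gen, seed=config.seed)
    return table


def _run_stages(config, table, specs, grid, age_bands, out, caught, errors):
    summarize_cohort(table, specs).to_csv(out / "summary.csv", float_format="%.10g")
    type_map = AdmissionTypeMap()

    # a comparison defined on a strata component cannot reweight across
    # that component: drop it from the strata grid for that comparison
    own_component = {"age": "age", "sex": "sex", "deprivation": "simd"}

    for ci, spec in enumerate(specs):
        comp_dir = out / spec.variable
        comp_dir.mkdir(exist_ok=True)
        mask_a, mask_b = group_masks(table, spec)
        members = {spec.label_a: mask_a, spec.label_b: mask_b}
        components = tuple(
            c for c in ALL_COMPONENTS if c != own_component.get(spec.variable)
        )

        def stage(name: str, mi: int, fn):
            try:
                fn(_stage_rng(config.seed, ci, mi))
            except Exception as exc:  # stage isolation
                msg = f"{spec.variable}/{name}: {type(exc).__name__}: {exc}"
                errors.append(msg)
                logger.error(msg)

        def parity_stage(rng):
            curves = {}
            for lab, m in members.items():
                if not m.any():
                    raise ValueError(f"group {lab!r} is empty")
                c = score_cdf(table.df.loc[m, "score"].to_numpy(), grid, group=lab)
                c.write(comp_dir / f"cdf_{lab}.csv")
                curves[lab] = c
            curve_difference(
                curves[spec.label_a], curves[spec.label_b]
            ).write(comp_dir / "cdf_difference.csv")

        def counterfactual_stage(rng):
            pairs = [
                (spec.label_a, mask_a, mask_b, spec.label_b),
                (spec.label_b, mask_b, mask_a, spec.label_a),
            ]
            for target_lab, target, source, source_lab in pairs:
                c = counterfactual_cdf(
                    table, target, source, grid, age_bands,
                    components=components, n_boot=config.n_boot, rng=rng,
                    group=f"{source_lab}_as_{target_lab}",
                )
                c.write(comp_dir / f"counterfactual_cdf_{source_lab}_as_{target_lab}.csv")

        def roc_stage(rng):
            for lab, m in members.items():
                r = roc_points(
                    table.df.loc[m, "score"].to_numpy(),
                    table.df.loc[m, "outcome"].to_numpy(), grid, group=lab,
                )
                df = pd.DataFrame({"cutoff": r.cutoffs, "fpr": r.fpr, "tpr": r.tpr})
                df["auroc"] = r.auroc
                df["auroc_se"] = r.auroc_se
                df["se_estimator"] = r.se_estimator
                df.to_csv(comp_dir / f"roc_{lab}.csv", index=False,
                          float_format="%.10g")

        def calibration_stage(rng):
            for lab, m in members.items():
                c = calibration_curve(
                    table.df.loc[m, "score"].to_numpy(),
                    table.df.loc[m, "outcome"].to_numpy(),
                    n_bins=config.calibration_bins,
                    min_count=config.calibration_min_count, group=lab,
                )
                c.write(comp_dir / f"calibration_{lab}.csv")

        def rate_stage_factory(metric):
            def rate_stage(rng):
                raw = {}
                adj = {}
                for lab, m in members.items():
                    s = table.df.loc[m, "score"].to_numpy()
                    y = table.df.loc[m, "outcome"].to_numpy()
                    fn = for_curve if metric == "FOR" else fdr_curve
                    raw[lab] = fn(s, y, grid, group=lab)
                    raw[lab].write(comp_dir / f"{metric.lower()}_{lab}.csv")
                    other = mask_b if lab == spec.label_a else mask_a
                    req = RateCurveRequest(
                        metric, grid, adjustment="standardised",
                        reference=config.reference, age_bands=age_bands,
                        components=components, n_boot=config.n_boot,
                    )
                    adj[lab] = adjusted_rate_curve(
                        table, m, req, other_rows=other, rng=rng, group=lab
                    )
                    adj[lab].write(comp_dir / f"{metric.lower()}_adjusted_{lab}.csv")
                curve_difference(raw[spec.label_a], raw[spec.label_b]).write(
                    comp_dir / f"{metric.lower()}_difference.csv"
                )
                curve_difference(adj[spec.label_a], adj[spec.label_b]).write(
                    comp_dir / f"{metric.lower()}_adjusted_difference.csv"
                )
            return rate_stage

        def decomposition_stage(rng):
            for lab, m in members.items():
                t = decomposition_table(
                    table, m, threshold=config.fn_threshold, type_map=type_map,
                    n_boot=config.n_boot, rng=rng, group=lab,
                )
                t.to_csv(comp_dir / f"decomposition_{lab}.csv", index=False,
                         float_format="%.10g")

        stage("parity", 0, parity_stage)
        stage("counterfactual", 1, counterfactual_stage)
        stage("roc", 2, roc_stage)
        stage("calibration", 3, calibration_stage)
        stage("for", 4, rate_stage_factory("FOR"))
        stage("fdr", 5, rate_stage_factory("FDR"))
        stage("decomposition", 6, decomposition_stage)
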