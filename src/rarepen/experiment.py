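"""Configuration, seeding, orchestration and persistence for full runs.

A run is fully described by an :class:`ExperimentConfig` plus a master
seed.  Per-replicate seeds are spawned from the master seed with
``numpy``'s ``SeedSequence`` (one child per replicate, further split per
stage and per stochastic method), so any replicate can be re-executed in
isolation and parallel execution gives results identical to sequential.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from joblib import Parallel, delayed

from . import __version__
from .cohort import (CohortSample, ConfigurationError, ExposureSpec,
                     PopulationConfig, make_prevalence_grid,
                     simulate_replicate, write_cohort)
from .estimators import DEFAULT_ALPHA, METHODS
from .evaluation import ReplicateRecord, SummaryTables, build_summary_tables

#: methods whose fitting consumes randomness (CV folds, bootstrap)
_STOCHASTIC_METHODS = ("lasso", "ridge")


@dataclass
class ExperimentConfig:
    """All knobs of the simulation comparison, with the study defaults."""

    n_replicates: int = 100
    methods: tuple = ("ml", "firth", "ridge", "lasso", "boosting")
    # cohort generation
    n_pop: int = 100_000
    n_cases: int = 5_000
    n_controls: int = 5_000
    p_count: int = 50
    p_max: float = 0.03
    p_min: float = 5e-5
    snr: float = 3.0
    confounder_prevalence: float = 0.5
    intercept: float = 0.0
    # estimator tuning
    alpha: float = DEFAULT_ALPHA
    n_folds: int = 10
    n_bootstrap: int = 100
    m_max: int = 500
    boost_penalty: float = 200.0
    # run control
    master_seed: int = 0
    output_dir: str | None = None
    save_cohorts: bool = False
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d


def validate_config(config: ExperimentConfig) -> ExperimentConfig:
    """Bounds-check every field; warnings for feasible-only-in-expectation."""
    c = config
    if c.n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    unknown = [m for m in c.methods if m not in METHODS]
    if unknown:
        raise ConfigurationError(
            f"unknown methods {unknown}; available: {sorted(METHODS)}")
    if not c.methods:
        raise ConfigurationError("at least one method is required")
    # PopulationConfig and the grid perform their own validation
    PopulationConfig(n_pop=c.n_pop, intercept=c.intercept, snr=c.snr,
                     confounder_prevalence=c.confounder_prevalence)
    make_prevalence_grid(c.p_count, c.p_max, c.p_min)
    if min(c.n_cases, c.n_controls) < 1:
        raise ConfigurationError("n_cases and n_controls must be >= 1")
    if c.n_cases + c.n_controls > c.n_pop:
        raise ConfigurationError(
            f"n_cases + n_controls = {c.n_cases + c.n_controls} exceeds the "
            f"population size {c.n_pop}")
    if not 0.0 < c.alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {c.alpha}")
    if c.n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if c.n_bootstrap < 2:
        raise ConfigurationError("n_bootstrap must be >= 2")
    if c.m_max < 1:
        raise ConfigurationError("m_max must be >= 1")
    if c.boost_penalty <= 0:
        raise ConfigurationError("boost_penalty must be positive")
    expected_cases = c.n_pop * 0.5  # baseline outcome probability
    if max(c.n_cases, c.n_controls) > 0.8 * expected_cases:
        warnings.warn(
            "requested case/control counts are close to the expected number "
            "available in the population; sampling may fail for some seeds")
    return c


def default_spec(config: ExperimentConfig) -> ExposureSpec:
    """The exposure truth implied by a config's prevalence-grid settings."""
    grid = make_prevalence_grid(config.p_count, config.p_max, config.p_min)
    if config.p_count == 50:
        return ExposureSpec(grid)
    # for non-standard grids: 5 relevant exposures log-evenly spread by index
    idx = np.unique(np.round(np.linspace(0, config.p_count - 1, 5)).astype(int))
    signs = tuple(-1 if i % 2 == 0 else 1 for i in range(len(idx)))
    return ExposureSpec(grid, tuple(int(i) for i in idx), signs)


def replicate_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n)


def run_replicate(config: ExperimentConfig, spec: ExposureSpec,
                  replicate_id: int,
                  seed: np.random.SeedSequence) -> ReplicateRecord:
    """Simulate one cohort and fit every configured method on it."""
    s_sim, s_fit = seed.spawn(2)
    sample = simulate_replicate(
        spec,
        PopulationConfig(n_pop=config.n_pop, intercept=config.intercept,
                         snr=config.snr,
                         confounder_prevalence=config.confounder_prevalence),
        n_cases=config.n_cases, n_controls=config.n_controls, seed=s_sim)
    method_seeds = dict(zip(_STOCHASTIC_METHODS,
                            s_fit.spawn(len(_STOCHASTIC_METHODS))))
    record = ReplicateRecord(replicate_id=replicate_id, truth=spec)
    for m in config.methods:
        record.fits[m] = _fit_one(m, sample, config, method_seeds.get(m))
    record.sample = sample  # kept for callers that need the raw replicate
    return record


def _fit_one(method: str, sample: CohortSample, config: ExperimentConfig,
             seed):
    if method == "ml":
        return METHODS["ml"](sample, alpha=config.alpha)
    if method == "firth":
        return METHODS["firth"](sample, alpha=config.alpha)
    if method == "lasso":
        return METHODS["lasso"](sample, n_folds=config.n_folds, seed=seed)
    if method == "ridge":
        return METHODS["ridge"](sample, n_folds=config.n_folds,
                                B=config.n_bootstrap, seed=seed)
    if method == "boosting":
        return METHODS["boosting"](sample, M_max=config.m_max,
                                   lam=config.boost_penalty)
    raise ConfigurationError(f"unknown method {method!r}")


def run_experiment(config: ExperimentConfig,
                   spec: ExposureSpec | None = None):
    """Run the full comparison; returns (SummaryTables, manifest dict)."""
    config = validate_config(config)
    spec = spec or default_spec(config)
    seeds = replicate_seeds(config.master_seed, config.n_replicates)

    if config.n_jobs != 1:
        records = Parallel(n_jobs=config.n_jobs)(
            delayed(run_replicate)(config, spec, i, s)
            for i, s in enumerate(seeds))
    else:
        records = [run_replicate(config, spec, i, s)
                   for i, s in enumerate(seeds)]

    tables = build_summary_tables(records, methods=list(config.methods))
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_replicates": config.n_replicates,
        "methods": list(config.methods),
    }
    if config.output_dir is not None:
        _persist(Path(config.output_dir), config, records, tables, manifest)
    return tables, manifest, records


def _persist(out: Path, config: ExperimentConfig, records, tables, manifest):
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    tables.selection_relevant.to_csv(out / "selection_relevant.csv")
    tables.selection_irrelevant.to_csv(out / "selection_irrelevant.csv")
    tables.mean_bias.to_csv(out / "mean_bias.csv")
    tables.mse.to_csv(out / "mse.csv")
    cells = {
        "selection_relevant": tables.selection_relevant.to_dict(),
        "selection_relevant_se": tables.selection_relevant_se.to_dict(),
        "selection_irrelevant": tables.selection_irrelevant.to_dict(),
        "selection_irrelevant_se": tables.selection_irrelevant_se.to_dict(),
        "n_replicates": tables.n_replicates,
    }
    (out / "summary_cells.json").write_text(
        json.dumps(cells, indent=1, sort_keys=True))
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    for rec in records:
        for m, fit in rec.fits.items():
            fit.to_json(fits_dir / f"rep{rec.replicate_id:03d}_{m}.json")
        if config.save_cohorts and getattr(rec, "sample", None) is not None:
            write_cohort(rec.sample,
                         out / f"cohort_rep{rec.replicate_id:03d}.csv")
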