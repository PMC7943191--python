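"""End-to-end orchestration: scenario -> microdata -> summaries -> fits -> decomposition.

The pipeline either simulates a configured scenario or consumes user-supplied
stratum-summary and mean-trajectory CSVs in the documented schemas, then fits
the six probit regressions (2 sexes x 3 outcomes) and runs the counterfactual
decomposition. All artifacts are plain CSV/JSON; a run log records seeds,
filter counts, dropped design columns and per-stage timings. Identical
configuration and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .constants import AGE_BANDS, OUTCOMES, REGIONS, SEXES, standard_population_weights
from .decompose import run_decomposition
from .model import CoefficientTable, ModelSpec, fit_model, save_coefficients
from .summaries import apply_inclusion_filters, summarise_stratum_arrays, summarise_study
from .synthetic import (
    ConfigurationError,
    ScenarioConfig,
    make_mean_trajectories,
    make_scenario,
    sample_stratum,
)

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["region", "sex", "age_group", "mean_1985", "mean_2016"]


def _iter_studies(config: ScenarioConfig) -> Iterator[tuple[str, str, int, int]]:
    for region in REGIONS:
        for year in config.years:
            for s in range(config.studies_per_region_year):
                study_id = f"R{REGIONS.index(region)}-{year}-s{s}"
                yield study_id, region, year, s


def _study_offset(config: ScenarioConfig, region: str, year: int, study: int) -> float:
    """Persistent study-level shift of mean BMI (country/community heterogeneity)."""
    ss = np.random.SeedSequence(
        [int(config.seed), 1_000_003, REGIONS.index(region), int(year), int(study)]
    )
    return float(
        np.random.default_rng(ss).normal(0.0, config.study_mean_sd)
    )


def _stratum_stream(
    config: ScenarioConfig, region: str, sex: str, age: str, year: int, study: int
) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [
            int(config.seed),
            REGIONS.index(region),
            SEXES.index(sex),
            AGE_BANDS.index(age),
            int(year),
            int(study),
        ]
    )


def simulate_summaries(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a scenario and return (stratum summaries, mean trajectories).

    Microdata are sampled stratum by stratum and summarised immediately, so
    memory stays flat regardless of the number of participants. Each study
    carries a persistent location offset shared by all its strata, emulating
    the between-study heterogeneity of pooled multi-country data.
    """
    params = make_scenario(config)
    rows = []
    for study_id, region, year, s in _iter_studies(config):
        offset = _study_offset(config, region, year, s)
        for sex in SEXES:
            for age in AGE_BANDS:
                cell = params[(region, sex, age, year)]
                cell = dataclasses.replace(cell, location=cell.location + offset)
                micro = sample_stratum(
                    cell,
                    config.participants_per_stratum,
                    _stratum_stream(config, region, sex, age, year, s),
                    study_id=study_id,
                    weight_dist=config.weight_dist,
                )
                row = {
                    "study_id": study_id,
                    "region": region,
                    "sex": sex,
                    "age_group": age,
                    "year": year,
                }
                row.update(
                    summarise_stratum_arrays(
                        micro["bmi"].to_numpy(), micro["weight"].to_numpy()
                    )
                )
                rows.append(row)
    summaries = pd.DataFrame(rows)
    trajectories = make_mean_trajectories(params)
    return summaries, trajectories


def write_microdata_csv(config: ScenarioConfig, path: str | Path) -> int:
    """Stream scenario microdata to CSV (columns study_id, region, sex,
    age_group, year, bmi, weight); returns the number of rows written."""
    params = make_scenario(config)
    total = 0
    with open(path, "w") as fh:
        first = True
        for study_id, region, year, s in _iter_studies(config):
            offset = _study_offset(config, region, year, s)
            for sex in SEXES:
                for age in AGE_BANDS:
                    cell = params[(region, sex, age, year)]
                    cell = dataclasses.replace(cell, location=cell.location + offset)
                    micro = sample_stratum(
                        cell,
                        config.participants_per_stratum,
                        _stratum_stream(config, region, sex, age, year, s),
                        study_id=study_id,
                        weight_dist=config.weight_dist,
                    )
                    micro.to_csv(fh, index=False, header=first)
                    first = False
                    total += len(micro)
    return total


@dataclass
class PipelineConfig:
    """Run configuration: exactly one of a scenario or a pair of input CSVs."""

    scenario: ScenarioConfig | None = None
    strata_csv: str | None = None
    trajectories_csv: str | None = None
    outdir: str | Path = "results"
    min_abs_change: float = 1.0  # pp; relevance threshold for percent_explained
    weighted_fit: bool = False
    weights_csv: str | None = None  # optional standard-population override
    include_detail: bool = True

    def __post_init__(self) -> None:
        has_files = self.strata_csv is not None or self.trajectories_csv is not None
        if self.scenario is not None and has_files:
            raise ConfigurationError("provide either a scenario or input files, not both")
        if self.scenario is None:
            if self.strata_csv is None or self.trajectories_csv is None:
                raise ConfigurationError(
                    "without a scenario, both strata_csv and trajectories_csv are required"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            name = scenario.pop("scenario_name")
            scenario = ScenarioConfig.from_name(name, **scenario)
        return cls(scenario=scenario, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts under ``config.outdir``.

    Artifacts: ``strata.csv`` (stratum summaries), ``trajectories.csv``,
    ``exclusions.csv``, one ``coef_<sex>_<outcome>.csv`` per model,
    ``decomposition.csv`` and ``run_log.json``. Returns the in-memory results
    keyed by artifact name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}}
    t0 = time.perf_counter()

    if config.scenario is not None:
        summaries, trajectories = simulate_summaries(config.scenario)
        log["seed"] = config.scenario.seed
        log["scenario"] = config.scenario.scenario_name
    else:
        summaries = pd.read_csv(config.strata_csv)
        trajectories = pd.read_csv(config.trajectories_csv)
        missing = set(TRAJECTORY_COLUMNS) - set(trajectories.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    log["n_strata"] = int(len(summaries))
    log["stages"]["inputs_s"] = round(time.perf_counter() - t0, 3)

    weights = standard_population_weights(config.weights_csv)
    coefs: dict[tuple[str, str], CoefficientTable] = {}
    exclusion_logs = []
    t1 = time.perf_counter()
    for sex in SEXES:
        by_sex = summaries[summaries["sex"] == sex]
        for outcome in OUTCOMES:
            included, excl = apply_inclusion_filters(by_sex, outcome)
            exclusion_logs.append(excl)
            spec = ModelSpec(outcome=outcome, sex=sex, weighted=config.weighted_fit)
            coef = fit_model(included, spec)
            coefs[(sex, outcome)] = coef
            log.setdefault("fits", {})[f"{sex}_{outcome}"] = {
                "n_included": int(len(included)),
                "n_excluded": int(len(excl)),
                "r_squared": round(coef.r_squared, 6),
                "dropped_terms": list(coef.dropped),
            }
    log["stages"]["fits_s"] = round(time.perf_counter() - t1, 3)

    t2 = time.perf_counter()
    decomposition = run_decomposition(
        coefs,
        trajectories,
        weights=weights,
        min_abs_change=config.min_abs_change,
        include_detail=config.include_detail,
    )
    log["stages"]["decomposition_s"] = round(time.perf_counter() - t2, 3)
    log["stages"]["total_s"] = round(time.perf_counter() - t0, 3)

    exclusions = (
        pd.concat(exclusion_logs, ignore_index=True)
        if exclusion_logs
        else pd.DataFrame(columns=["study_id", "sex", "age_group", "year", "outcome", "reason"])
    )
    summaries.to_csv(outdir / "strata.csv", index=False)
    trajectories.to_csv(outdir / "trajectories.csv", index=False)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    for (sex, outcome), coef in coefs.items():
        save_coefficients(coef, outdir / f"coef_{sex}_{outcome}.csv")
    decomposition.to_csv(outdir / "decomposition.csv", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    logger.info("pipeline complete: %s", log["stages"])
    return {
        "summaries": summaries,
        "trajectories": trajectories,
        "exclusions": exclusions,
        "coefficients": coefs,
        "decomposition": decomposition,
        "log": log,
    }


def make_fixtures(seed: int = 0, outdir: str | Path | None = None):
    """Miniature but full-coverage dataset for tests and examples.

    A mixed scenario sampled at five years with one study per region-year
    (540 stratum rows) — small enough to regenerate in seconds, rich enough
    that every region, sex and age band survives filtering and all six
    regressions are identifiable.
    """
    config = ScenarioConfig.mixed(
        seed=seed,
        years=(1985, 1993, 2001, 2009, 2016),
        studies_per_region_year=1,
        participants_per_stratum=10_000,
    )
    summaries, trajectories = simulate_summaries(config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(outdir / "fixture_strata.csv", index=False)
        trajectories.to_csv(outdir / "fixture_trajectories.csv", index=False)
    return summaries, trajectories
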