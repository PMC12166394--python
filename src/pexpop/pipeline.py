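"""End-to-end prevalence pipeline.

Composes classification -> allele-class pooling -> expanded Hardy-Weinberg
genotype prevalence (with 90% modified-Wald ranges) -> phenotype
assignment -> country birth counts -> survival-based cohort aging, and
writes the birth report, rate report and age-by-phenotype prevalence
table for each configured region and model.

A prevalence cell is ``births(reference_year - age) * phenotype birth
frequency * S_phenotype(age)`` for ages 0..31; the headline "under 31"
total sums ages 0..30.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import popgen, survival, variants
from .popgen import AlleleClassFrequencies, GenotypeClassPrevalence
from .survival import (
    DEFAULT_ASSIGNMENT,
    MODEL_HORIZON_YEARS,
    PhenotypeAssignment,
    SurvivalSchedule,
)

__all__ = [
    "BirthSchedule",
    "PrevalenceTable",
    "births_per_year",
    "build_prevalence_table",
    "run_model",
    "RunResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BirthSchedule:
    """Live births per calendar year for one country."""

    country: str
    births_by_year: Mapping[int, int]
    reference_year: int = 2021
    allow_extrapolation: bool = True

    def __post_init__(self) -> None:
        if not self.births_by_year:
            raise ValueError(f"{self.country}: empty birth schedule")
        if any(b < 0 for b in self.births_by_year.values()):
            raise ValueError(f"{self.country}: negative birth count")

    def births(self, year: int) -> int:
        if year in self.births_by_year:
            return self.births_by_year[year]
        if not self.allow_extrapolation:
            raise KeyError(
                f"{self.country}: no birth count for {year} and "
                "extrapolation disabled"
            )
        nearest = min(self.births_by_year, key=lambda y: abs(y - year))
        if not getattr(self, "_warned", False):
            logger.warning(
                "%s: birth series does not cover all modelled years; "
                "constant-extrapolating from nearest configured year "
                "(first instance: %d from %d)",
                self.country, year, nearest,
            )
            object.__setattr__(self, "_warned", True)
        return self.births_by_year[nearest]


@dataclass(frozen=True)
class PrevalenceTable:
    """Expected persons alive at the reference year by age and phenotype."""

    country: str
    model: str
    cells: pd.DataFrame  # columns: age, phenotype, persons

    @property
    def totals_by_phenotype(self) -> dict[str, float]:
        return self.cells.groupby("phenotype")["persons"].sum().to_dict()

    def total(self, max_age: int = MODEL_HORIZON_YEARS) -> float:
        return float(self.cells.loc[self.cells["age"] <= max_age, "persons"].sum())

    @property
    def total_under_31(self) -> float:
        return self.total(30)


def births_per_year(
    phenotype_freqs: Mapping[str, float], births: int
) -> dict[str, float]:
    """Expected affected births per phenotype for one birth-year cohort."""
    if births < 0:
        raise ValueError("births must be non-negative")
    return {p: f * births for p, f in phenotype_freqs.items()}


def build_prevalence_table(
    phenotype_freqs: Mapping[str, float],
    birth_schedule: BirthSchedule,
    schedules: Mapping[str, SurvivalSchedule] = survival.DEFAULT_SCHEDULES,
    model: str = "core",
) -> PrevalenceTable:
    """Age affected birth cohorts to the reference year.

    Deterministic: each (age, phenotype) cell is the affected births of
    the cohort born ``reference_year - age`` scaled by cumulative survival
    to that age.
    """
    ref = birth_schedule.reference_year
    rows = []
    for age in range(MODEL_HORIZON_YEARS + 1):
        births = birth_schedule.births(ref - age)
        for phenotype, freq in phenotype_freqs.items():
            s = survival.cumulative_survival(schedules[phenotype], age)
            rows.append(
                {"age": age, "phenotype": phenotype, "persons": births * freq * s}
            )
    return PrevalenceTable(birth_schedule.country, model, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Config-driven run
# ---------------------------------------------------------------------------


@dataclass
class RegionResult:
    region: str
    model: str
    freqs: AlleleClassFrequencies
    genotypes: list[GenotypeClassPrevalence]
    q_total: float
    q_ci: popgen.ConfidenceInterval
    phenotype_freqs: dict[str, float]
    births_report_row: dict
    prevalence: PrevalenceTable


@dataclass
class RunResult:
    births_report: pd.DataFrame
    genotype_report: pd.DataFrame
    prevalence: pd.DataFrame
    manifest: dict
    regions: list[RegionResult] = field(default_factory=list)


def _config_dict(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_model(config, out_dir: str | Path | None = None) -> RunResult:
    """Run the full pipeline from a config mapping or YAML path.

    Config keys: ``variants`` (table path) or ``variant_records``,
    ``regions`` ({name: {cohorts, births_by_year}}), ``models``
    (subset of core/expanded), ``af_threshold``, ``level``,
    ``split_fraction``, ``assignment_mode`` (expected/sampled), ``seed``,
    ``reference_year``, ``survival`` (band overrides).  Writes
    births_report.tsv, genotypes.tsv, prevalence.tsv and manifest.json
    when ``out_dir`` is given; reruns with the same config and seed are
    byte-identical.
    """
    cfg = _config_dict(config)
    af_threshold = float(cfg.get("af_threshold", variants.DEFAULT_AF_THRESHOLD))
    level = float(cfg.get("level", 0.90))
    split = float(cfg.get("split_fraction", 0.5))
    mode = cfg.get("assignment_mode", "expected")
    seed = cfg.get("seed", 0)
    reference_year = int(cfg.get("reference_year", 2021))
    models = list(cfg.get("models", ["core", "expanded"]))
    schedules = survival.schedules_from_config(cfg.get("survival"))
    assignment = PhenotypeAssignment(
        dict(DEFAULT_ASSIGNMENT.mapping), split_fraction_intermediate=split
    )

    if "variant_records" in cfg:
        records = list(cfg["variant_records"])
    else:
        loaded = variants.load_variant_table(
            cfg["variants"], cfg.get("dialect", "tsv")
        )
        if loaded.errors:
            for i, msg in loaded.errors:
                logger.warning("variant table row %d skipped: %s", i, msg)
        records = loaded.records

    births_rows, genotype_rows, prevalence_frames = [], [], []
    region_results: list[RegionResult] = []
    for region, rcfg in cfg["regions"].items():
        cohorts = list(rcfg["cohorts"])
        labeled = variants.classify_table(records, af_threshold, cohorts)
        birth_schedule = BirthSchedule(
            region,
            {int(y): int(b) for y, b in rcfg["births_by_year"].items()},
            reference_year,
            allow_extrapolation=bool(rcfg.get("allow_extrapolation", True)),
        )
        for model in models:
            try:
                result = _run_region_model(
                    region, model, labeled, cohorts, birth_schedule,
                    schedules, assignment, level, mode, seed,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"[region={region} model={model}] {exc}"
                ) from exc
            region_results.append(result)
            births_rows.append(result.births_report_row)
            for g in result.genotypes:
                genotype_rows.append(
                    {
                        "region": region,
                        "model": model,
                        "genotype_class_i": g.class_a,
                        "genotype_class_j": g.class_b,
                        "frequency": g.frequency,
                        "ci90_lo": g.ci_lo,
                        "ci90_hi": g.ci_hi,
                    }
                )
            frame = result.prevalence.cells.copy()
            frame.insert(0, "model", model)
            frame.insert(0, "country", region)
            prevalence_frames.append(frame)

    result = RunResult(
        births_report=pd.DataFrame(births_rows),
        genotype_report=pd.DataFrame(genotype_rows),
        prevalence=pd.concat(prevalence_frames, ignore_index=True),
        manifest=_manifest(cfg, af_threshold, level, split, mode, seed, models),
        regions=region_results,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _run_region_model(
    region, model, labeled, cohorts, birth_schedule, schedules, assignment,
    level, mode, seed,
) -> RegionResult:
    freqs = popgen.aggregate_allele_classes(labeled, region, cohorts, model)
    genotypes = popgen.expanded_hw(freqs.q)
    genotypes = popgen.attach_genotype_cis(genotypes, freqs, level)
    q_total, q_ci = popgen.prevalence_ci(freqs, level)
    pheno = survival.assign_phenotypes(genotypes, assignment, mode, seed)
    births_ref = birth_schedule.births(birth_schedule.reference_year)
    affected = births_per_year(pheno, births_ref)
    rate = popgen.rates(q_total)
    rate_lo, rate_hi = popgen.rates(q_ci.lo), popgen.rates(q_ci.hi)
    total_births = q_total * births_ref
    row = {
        "country": region,
        "model": model,
        # Whole-number best estimate (banker's rounding), CI at one decimal.
        "births_estimate": round(total_births),
        "births_lo": round(q_ci.lo * births_ref, 1),
        "births_hi": round(q_ci.hi * births_ref, 1),
        "births_exact": total_births,
        "per_million": rate.per_million,
        "per_million_lo": rate_lo.per_million,
        "per_million_hi": rate_hi.per_million,
        "one_in_n": rate.one_in_n,
        **{f"births_{p}": affected[p] for p in survival.PHENOTYPES},
    }
    table = build_prevalence_table(pheno, birth_schedule, schedules, model)
    return RegionResult(
        region, model, freqs, genotypes, q_total, q_ci, pheno, row, table
    )


def _manifest(cfg, af_threshold, level, split, mode, seed, models) -> dict:
    from . import __version__

    canonical = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(canonical).hexdigest(),
        "seed": seed,
        "af_threshold": af_threshold,
        "confidence_level": level,
        "split_fraction_intermediate": split,
        "assignment_mode": mode,
        "models": models,
        "horizon_years": MODEL_HORIZON_YEARS,
    }


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.births_report.to_csv(out_dir / "births_report.tsv", sep="\t", index=False)
    result.genotype_report.to_csv(out_dir / "genotypes.tsv", sep="\t", index=False)
    result.prevalence.to_csv(out_dir / "prevalence.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
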