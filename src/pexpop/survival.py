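"""Genotype-to-phenotype assignment and phenotype-specific survival.

Phenotype map (defaults): homozygous null genotypes are severe, the
null/G843D compound heterozygote is intermediate, and homozygous G843D is
mild.  Rare genotype pairs without an established clinical assignment fall
in a combined intermediate-or-mild bucket: for modelling, half of that mass
presents as intermediate and half as mild (configurable split, and a
seeded sampled mode that assigns whole genotype segments at random).

Survival is piecewise-constant annual survival by age band, applied to
completed years of life and modelled to a horizon of 31 years:

* severe:        76.0% per year (generally not surviving past ~5 years)
* intermediate:  96.6% for years 1-8, 99.2% for years 9-18, 98.0% from 19
* mild:          99.4% per year (near-normal over the modelled window)

``fit_annual_survival`` recovers a constant annual rate from published
Kaplan-Meier points via origin-anchored least squares on ln S(t) = beta t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .popgen import GenotypeClassPrevalence

__all__ = [
    "PHENOTYPES",
    "MODEL_HORIZON_YEARS",
    "SurvivalSchedule",
    "PhenotypeAssignment",
    "DEFAULT_SCHEDULES",
    "DEFAULT_ASSIGNMENT",
    "assign_phenotypes",
    "cumulative_survival",
    "fit_annual_survival",
    "schedules_from_config",
]

PHENOTYPES = ("severe", "intermediate", "mild")
MODEL_HORIZON_YEARS = 31


@dataclass(frozen=True)
class SurvivalSchedule:
    """Piecewise annual survival for one phenotype.

    ``bands`` is an ordered list of (age_from, age_to, annual_survival)
    with inclusive integer year bounds, contiguous from year 1 through the
    model horizon.
    """

    phenotype: str
    bands: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        expected_start = 1
        for age_from, age_to, s in self.bands:
            if age_from != expected_start:
                raise ValueError(
                    f"{self.phenotype}: bands must be contiguous from age 1 "
                    f"(expected start {expected_start}, got {age_from})"
                )
            if age_to < age_from:
                raise ValueError(f"{self.phenotype}: empty band {age_from}-{age_to}")
            if not 0 < s <= 1:
                raise ValueError(
                    f"{self.phenotype}: annual survival {s} outside (0, 1]"
                )
            expected_start = age_to + 1
        if expected_start <= MODEL_HORIZON_YEARS:
            raise ValueError(
                f"{self.phenotype}: schedule ends at year {expected_start - 1}, "
                f"must reach the {MODEL_HORIZON_YEARS}-year horizon"
            )

    def annual(self, year: int) -> float:
        for age_from, age_to, s in self.bands:
            if age_from <= year <= age_to:
                return s
        raise ValueError(f"{self.phenotype}: year {year} beyond schedule")

    def cumulative(self, age: int) -> float:
        return cumulative_survival(self, age)


def cumulative_survival(schedule: SurvivalSchedule, age: int) -> float:
    """Probability of surviving from birth to a given completed age.

    S(0) = 1 and S(a) multiplies the annual factors of years 1..a; the
    model horizon is 31 years.
    """
    if not 0 <= age <= MODEL_HORIZON_YEARS:
        raise ValueError(
            f"age {age} outside modelled range 0..{MODEL_HORIZON_YEARS}"
        )
    s = 1.0
    for year in range(1, age + 1):
        s *= schedule.annual(year)
    return s


DEFAULT_SCHEDULES: dict[str, SurvivalSchedule] = {
    "severe": SurvivalSchedule("severe", ((1, MODEL_HORIZON_YEARS, 0.760),)),
    "intermediate": SurvivalSchedule(
        "intermediate",
        ((1, 8, 0.966), (9, 18, 0.992), (19, MODEL_HORIZON_YEARS, 0.980)),
    ),
    "mild": SurvivalSchedule("mild", ((1, MODEL_HORIZON_YEARS, 0.994),)),
}


def schedules_from_config(config: Mapping) -> dict[str, SurvivalSchedule]:
    """Build schedules from {phenotype: [{from, to, annual}, ...]} mappings."""
    out = dict(DEFAULT_SCHEDULES)
    for phenotype, bands in (config or {}).items():
        out[phenotype] = SurvivalSchedule(
            phenotype,
            tuple((int(b["from"]), int(b["to"]), float(b["annual"])) for b in bands),
        )
    return out


INTERMEDIATE_OR_MILD = "intermediate_or_mild"


@dataclass(frozen=True)
class PhenotypeAssignment:
    """Map from unordered allele-class pairs to expected phenotype.

    Unknown pairs default to the combined intermediate-or-mild bucket,
    split ``split_fraction_intermediate`` : (1 - that) between intermediate
    and mild.
    """

    mapping: Mapping[frozenset, str] = field(
        default_factory=lambda: dict(_DEFAULT_MAP)
    )
    split_fraction_intermediate: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.split_fraction_intermediate <= 1:
            raise ValueError("split_fraction_intermediate must be in [0, 1]")

    def resolve(self, class_a: str, class_b: str) -> str:
        return self.mapping.get(frozenset((class_a, class_b)), INTERMEDIATE_OR_MILD)


_DEFAULT_MAP: dict[frozenset, str] = {
    frozenset({"NULL"}): "severe",
    frozenset({"NULL", "G843D"}): "intermediate",
    frozenset({"G843D"}): "mild",
}

DEFAULT_ASSIGNMENT = PhenotypeAssignment()


def assign_phenotypes(
    genotypes: Iterable[GenotypeClassPrevalence],
    assignment: PhenotypeAssignment = DEFAULT_ASSIGNMENT,
    mode: str = "expected",
    seed: int | None = None,
) -> dict[str, float]:
    """Convert genotype-class birth frequencies to a phenotype vector.

    ``expected`` mode splits intermediate-or-mild mass deterministically by
    the assignment's split fraction; ``sampled`` mode assigns each such
    genotype segment wholly to intermediate or mild by a seeded draw.
    Total frequency is conserved in both modes.
    """
    if mode not in ("expected", "sampled"):
        raise ValueError(f"mode must be 'expected' or 'sampled', got {mode!r}")
    rng = np.random.default_rng(seed) if mode == "sampled" else None
    split = assignment.split_fraction_intermediate
    out = {p: 0.0 for p in PHENOTYPES}
    for g in genotypes:
        phenotype = assignment.resolve(g.class_a, g.class_b)
        if phenotype in PHENOTYPES:
            out[phenotype] += g.frequency
        elif phenotype == INTERMEDIATE_OR_MILD:
            if rng is None:
                out["intermediate"] += split * g.frequency
                out["mild"] += (1 - split) * g.frequency
            else:
                target = "intermediate" if rng.random() < split else "mild"
                out[target] += g.frequency
        else:
            raise ValueError(f"unknown phenotype {phenotype!r} in assignment map")
    return out


def fit_annual_survival(km_points: Sequence[tuple[float, float]]) -> float:
    """Constant annual survival from Kaplan-Meier (time, survival) points.

    Fits the exponential model ln S = beta * t by least squares through the
    origin (S(0) = 1 is exact, so the fit is anchored there) and returns
    exp(beta), the annual survival fraction.
    """
    if len(km_points) < 2:
        raise ValueError("need at least 2 Kaplan-Meier points")
    times = np.asarray([t for t, _ in km_points], dtype=float)
    surv = np.asarray([s for _, s in km_points], dtype=float)
    if np.any(surv <= 0) or np.any(surv > 1):
        raise ValueError("survival fractions must be in (0, 1]")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if len(np.unique(times)) < 2:
        raise ValueError("need at least 2 distinct time points")
    denom = float(np.sum(times**2))
    beta = float(np.sum(times * np.log(surv))) / denom
    return math.exp(beta)
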