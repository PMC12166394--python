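"""Allele-class pooling, expanded Hardy-Weinberg genotype prevalence and
modified-Wald confidence ranges.

Pathogenic alleles are grouped into five classes: NULL (loss-of-function
alleles, known or high-confidence predicted), G843D (the common hypomorphic
p.(Gly843Asp) allele), MISSENSE_KNOWN (other ClinVar-pathogenic missense),
PREDICTED_SPLICE and PREDICTED_MISSENSE.  Under the expanded Hardy-Weinberg
principle an unordered genotype (i, j) occurs at birth with frequency
q_i^2 when i = j and 2 q_i q_j otherwise, so the total affected birth
frequency is Q = (sum_c q_c)^2.

Uncertainty: a modified-Wald (Agresti-Coull) binomial interval is placed on
the TOTAL pathogenic allele frequency p = X/AN and squared to give the
range on Q; per-genotype-class ranges scale each class frequency by
(p_lo/p)^2 and (p_hi/p)^2 so that classes stay internally consistent.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .variants import ClassLabel, CohortCounts, Tier, VariantRecord

__all__ = [
    "AlleleClass",
    "AlleleClassFrequencies",
    "GenotypeClassPrevalence",
    "ConfidenceInterval",
    "Rates",
    "pool_cohorts",
    "allele_class_of",
    "aggregate_allele_classes",
    "expanded_hw",
    "modified_wald_ci",
    "prevalence_ci",
    "attach_genotype_cis",
    "rates",
]


class AlleleClass(str, enum.Enum):
    NULL = "NULL"
    G843D = "G843D"
    MISSENSE_KNOWN = "MISSENSE_KNOWN"
    PREDICTED_SPLICE = "PREDICTED_SPLICE"
    PREDICTED_MISSENSE = "PREDICTED_MISSENSE"


_G843D_PATTERN = re.compile(r"Gly843Asp|G843D", re.IGNORECASE)


def pool_cohorts(counts: Sequence[CohortCounts]) -> tuple[int, int, float]:
    """Pool disjoint cohorts: (sum AC, sum AN, pooled frequency).

    Cohorts are assumed to be disjoint samples; a duplicated cohort name is
    a hard error because pooling the same sample twice biases q.
    """
    if not counts:
        raise ValueError("cannot pool an empty cohort list")
    names = [c.cohort for c in counts]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate cohort names in pool: {dupes}")
    ac = sum(c.allele_count for c in counts)
    an = sum(c.allele_number for c in counts)
    return ac, an, ac / an


def allele_class_of(record: VariantRecord, label: ClassLabel) -> AlleleClass | None:
    """Map an included variant to its allele class; ``None`` if excluded.

    Known-pathogenic LOF consequences join the NULL class alongside
    high-confidence pLOF; the p.(Gly843Asp) record is its own class; any
    other known-pathogenic variant counts as known missense.
    """
    from .variants import ESSENTIAL_LOF_CONSEQUENCES

    if label.tier == Tier.PLOF_HIGH_CONFIDENCE:
        return AlleleClass.NULL
    if label.tier == Tier.KNOWN_PATHOGENIC:
        if record.consequence in ESSENTIAL_LOF_CONSEQUENCES:
            return AlleleClass.NULL
        if _G843D_PATTERN.search(record.hgvs_p or ""):
            return AlleleClass.G843D
        return AlleleClass.MISSENSE_KNOWN
    if label.tier == Tier.PREDICTED_SPLICE:
        return AlleleClass.PREDICTED_SPLICE
    if label.tier == Tier.PREDICTED_MISSENSE:
        return AlleleClass.PREDICTED_MISSENSE
    return None


@dataclass(frozen=True)
class AlleleClassFrequencies:
    """Pooled allele counts per class over one region's cohorts.

    ``pooled_an`` is the common denominator: the sum over region cohorts of
    each cohort's maximum observed allele number (exact when per-cohort AN
    is constant across sites, conservative when call rates vary).
    """

    region: str
    pooled_an: int
    pooled_ac: Mapping[AlleleClass, int]

    def __post_init__(self) -> None:
        if self.pooled_an <= 0:
            raise ValueError("pooled_an must be positive")
        if any(ac < 0 for ac in self.pooled_ac.values()):
            raise ValueError("negative pooled allele count")

    @property
    def q(self) -> dict[AlleleClass, float]:
        return {c: ac / self.pooled_an for c, ac in self.pooled_ac.items()}

    @property
    def total_ac(self) -> int:
        return sum(self.pooled_ac.values())

    @property
    def total_q(self) -> float:
        return self.total_ac / self.pooled_an


def aggregate_allele_classes(
    labeled: Iterable[tuple[VariantRecord, ClassLabel]],
    region: str,
    region_cohorts: Sequence[str],
    model: str = "core",
) -> AlleleClassFrequencies:
    """Sum member-variant allele counts per class for one model.

    Variants whose membership does not include ``model`` contribute
    nothing; core is therefore always a subset of expanded.
    """
    if model not in ("core", "expanded"):
        raise ValueError(f"model must be 'core' or 'expanded', got {model!r}")
    pooled_ac: dict[AlleleClass, int] = {c: 0 for c in AlleleClass}
    max_an: dict[str, int] = {name: 0 for name in region_cohorts}
    for record, label in labeled:
        for name in region_cohorts:
            counts = record.cohorts.get(name)
            if counts is not None:
                max_an[name] = max(max_an[name], counts.allele_number)
        if not label.in_model(model):
            continue
        cls = allele_class_of(record, label)
        if cls is None:
            raise ValueError(
                f"variant {record.key} has membership {set(label.membership)} "
                "but no allele class"
            )
        ac, _, _ = record.pooled(region_cohorts)
        pooled_ac[cls] += ac
    pooled_an = sum(max_an.values())
    if pooled_an == 0:
        raise ValueError(f"no allele-number data for cohorts {list(region_cohorts)}")
    return AlleleClassFrequencies(region, pooled_an, pooled_ac)


@dataclass(frozen=True)
class GenotypeClassPrevalence:
    """Birth frequency of one unordered allele-class pair."""

    class_a: str
    class_b: str
    frequency: float
    ci_lo: float | None = None
    ci_hi: float | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.class_a, self.class_b)


def expanded_hw(q: Mapping) -> list[GenotypeClassPrevalence]:
    """Expanded Hardy-Weinberg genotype frequencies for all allele classes.

    Returns every unordered pair with nonzero frequency: q_i^2 for
    homozygous, 2 q_i q_j for compound-heterozygous genotypes.  The
    frequencies sum exactly to (sum q)^2.
    """
    items = [(getattr(c, "value", str(c)), float(v)) for c, v in q.items()]
    if any(v < 0 for _, v in items):
        raise ValueError("allele-class frequencies must be non-negative")
    if sum(v for _, v in items) > 1 + 1e-12:
        raise ValueError("allele-class frequencies sum above 1")
    out: list[GenotypeClassPrevalence] = []
    for i, (ci, qi) in enumerate(items):
        for cj, qj in items[i:]:
            freq = qi * qi if ci == cj else 2 * qi * qj
            if freq > 0:
                out.append(GenotypeClassPrevalence(ci, cj, freq))
    return out


@dataclass(frozen=True)
class ConfidenceInterval:
    level: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if self.lo > self.hi:
            raise ValueError("lo > hi")


def modified_wald_ci(x: int, n: int, level: float = 0.90) -> ConfidenceInterval:
    """Modified-Wald (Agresti-Coull) binomial confidence interval.

    With z the standard-normal quantile at 1 - (1-level)/2, the adjusted
    estimate is p' = (x + z^2/2) / (n + z^2) and the half-width
    z * sqrt(p'(1-p') / (n + z^2)); the interval is clipped to [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, n={n}]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(1 - (1 - level) / 2)
    n_adj = n + z * z
    p_adj = (x + z * z / 2) / n_adj
    half = z * math.sqrt(p_adj * (1 - p_adj) / n_adj)
    return ConfidenceInterval(level, max(0.0, p_adj - half), min(1.0, p_adj + half))


def prevalence_ci(
    freqs: AlleleClassFrequencies, level: float = 0.90
) -> tuple[float, ConfidenceInterval]:
    """Total affected-genotype frequency Q with its squared-Wald range.

    The interval on the total pathogenic allele frequency p = X/AN is
    squared: Q in (p_lo^2, p_hi^2).  With X = 0 the interval degenerates to
    (0, p_hi^2).
    """
    x, an = freqs.total_ac, freqs.pooled_an
    p_ci = modified_wald_ci(x, an, level)
    q_hat = freqs.total_q**2
    lo = 0.0 if x == 0 else p_ci.lo**2
    return q_hat, ConfidenceInterval(level, lo, p_ci.hi**2)


def attach_genotype_cis(
    genotypes: Sequence[GenotypeClassPrevalence],
    freqs: AlleleClassFrequencies,
    level: float = 0.90,
) -> list[GenotypeClassPrevalence]:
    """Scale each genotype-class frequency into its confidence range.

    Each class frequency f is mapped to (f*(p_lo/p)^2, f*(p_hi/p)^2) where
    p is the total pathogenic allele frequency, keeping per-class ranges
    proportional to the total-Q range.
    """
    p_hat = freqs.total_q
    if p_hat == 0:
        return [
            GenotypeClassPrevalence(g.class_a, g.class_b, g.frequency, 0.0, 0.0)
            for g in genotypes
        ]
    p_ci = modified_wald_ci(freqs.total_ac, freqs.pooled_an, level)
    lo_scale = (p_ci.lo / p_hat) ** 2
    hi_scale = (p_ci.hi / p_hat) ** 2
    return [
        GenotypeClassPrevalence(
            g.class_a,
            g.class_b,
            g.frequency,
            g.frequency * lo_scale,
            min(1.0, g.frequency * hi_scale),
        )
        for g in genotypes
    ]


@dataclass(frozen=True)
class Rates:
    per_million: float
    one_in_n: float | None  # None when Q = 0 (undefined, flagged)


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    digits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, digits)


def rates(q_total: float) -> Rates:
    """Convert a birth frequency Q to per-million and 1-in-N rates.

    ``one_in_n`` is 1/Q rounded to three significant figures; undefined
    (``None``) when Q = 0.
    """
    if q_total < 0:
        raise ValueError("Q must be non-negative")
    if q_total == 0:
        return Rates(0.0, None)
    return Rates(q_total * 1e6, _round_sig(1.0 / q_total, 3))
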