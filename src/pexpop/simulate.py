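"""Synthetic cohorts with known ground truth.

Generates every input the pipeline consumes without touching external
resources: variant annotation tables whose allele counts are binomial
draws around planted true frequencies, decoy variants built to fail
exactly one classification rule each, multinomial patient cohorts drawn
from model genotype proportions, and a recovery harness that measures
bias and confidence-interval coverage of the end-to-end estimate.

Randomness: each planted variant draws from its own integer-seeded RNG
stream (``default_rng([seed, index])``) so tables are reproducible
per-variant and across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import popgen, variants
from .compare import ObservedGenotypeCounts
from .popgen import AlleleClass
from .variants import MISSENSE_PREDICTORS, Tier

__all__ = [
    "PlantedVariant",
    "TruthSpec",
    "template",
    "paper_like_spec",
    "recovery_spec",
    "simulate_cohort",
    "simulate_patients",
    "recovery_harness",
    "RecoveryReport",
]

_MAX_TOTAL_PATHOGENIC_Q = 0.02
_MIN_COHORT_AN = 10_000


def template(
    kind: str,
    *,
    consequence: str | None = None,
    clinvar: str = "absent",
    hgvs_c: str = "",
    hgvs_p: str = "",
    spliceai: float | None = None,
    calls: Sequence[str | None] | None = None,
) -> dict:
    """Annotation template for a planted variant.

    ``kind`` picks sensible defaults per tier: ``known_pathogenic_lof``,
    ``known_pathogenic_missense``, ``plof``, ``splice``, ``missense``,
    ``benign``, ``synonymous``.
    """
    defaults = {
        "known_pathogenic_lof": dict(
            consequence="frameshift_variant", clinvar="pathogenic"
        ),
        "known_pathogenic_missense": dict(
            consequence="missense_variant", clinvar="pathogenic"
        ),
        "plof": dict(consequence="stop_gained", clinvar="absent"),
        "splice": dict(consequence="intron_variant", clinvar="absent", spliceai=0.92),
        "missense": dict(
            consequence="missense_variant",
            clinvar="absent",
            calls=("deleterious",) * 4,
        ),
        "benign": dict(consequence="missense_variant", clinvar="benign"),
        "synonymous": dict(consequence="synonymous_variant", clinvar="absent"),
    }
    if kind not in defaults:
        raise ValueError(f"unknown template kind {kind!r}")
    t = dict(defaults[kind])
    if consequence is not None:
        t["consequence"] = consequence
    if clinvar != "absent" or "clinvar" not in t:
        t["clinvar"] = clinvar
    if spliceai is not None:
        t["spliceai"] = spliceai
    if calls is not None:
        t["calls"] = tuple(calls)
    t.setdefault("spliceai", None)
    t.setdefault("calls", (None,) * 4)
    t["hgvs_c"], t["hgvs_p"] = hgvs_c, hgvs_p
    return t


@dataclass(frozen=True)
class PlantedVariant:
    name: str
    q_true: float
    allele_class: AlleleClass | None  # None for decoys
    template: Mapping
    expected_tier: Tier
    #: None draws hom_count ~ Binomial(AN/2, q^2); an integer fixes it, so a
    #: decoy can trip (or be kept clear of) the homozygote rule alone.
    hom_override: int | None = None


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for one simulated region."""

    region: str
    cohort_an: Mapping[str, int]
    planted: tuple[PlantedVariant, ...]

    def __post_init__(self) -> None:
        total_q = sum(v.q_true for v in self.planted if v.allele_class is not None)
        if total_q > _MAX_TOTAL_PATHOGENIC_Q:
            raise ValueError(
                f"total planted pathogenic frequency {total_q} above "
                f"{_MAX_TOTAL_PATHOGENIC_Q}"
            )
        for name, an in self.cohort_an.items():
            if an < _MIN_COHORT_AN:
                raise ValueError(f"cohort {name}: AN {an} below {_MIN_COHORT_AN}")

    @property
    def cohorts(self) -> list[str]:
        return list(self.cohort_an)

    def q_class_true(self, model: str = "expanded") -> dict[AlleleClass, float]:
        core_tiers = (Tier.KNOWN_PATHOGENIC, Tier.PLOF_HIGH_CONFIDENCE)
        out: dict[AlleleClass, float] = {}
        for v in self.planted:
            if v.allele_class is None:
                continue
            if model == "core" and v.expected_tier not in core_tiers:
                continue
            out[v.allele_class] = out.get(v.allele_class, 0.0) + v.q_true
        return out

    def q_total_true(self, model: str = "expanded") -> float:
        return sum(self.q_class_true(model).values())


def paper_like_spec(region: str = "US") -> TruthSpec:
    """Preset emulating a US-like variant landscape.

    Allele-class truth: NULL 1.1e-3 (three LOF variants, dominated by an
    I700fs-like frameshift), G843D 9e-4, known missense 5e-5, predicted
    splice 3e-4, predicted missense 6.5e-4.  Core pathogenic allele
    frequency is thus 2.05e-3 (Q_core ~ 4.2e-6, about 1 affected birth in
    240,000) and expanded 3.0e-3 (Q_expanded 9e-6); fixture choices that
    match the order of magnitude of a large-country core model.  Decoys
    each fail exactly one classification rule.
    """
    mk = PlantedVariant
    planted = (
        mk("I700fs_like", 6e-4, AlleleClass.NULL,
           template("known_pathogenic_lof", hgvs_c="c.2097dup", hgvs_p="p.(Ile700fs*42)"),
           Tier.KNOWN_PATHOGENIC),
        mk("R633X_like", 2e-4, AlleleClass.NULL,
           template("known_pathogenic_lof", consequence="stop_gained",
                    hgvs_c="c.1897C>T", hgvs_p="p.(Arg633Ter)"),
           Tier.KNOWN_PATHOGENIC),
        mk("novel_splice_donor", 3e-4, AlleleClass.NULL,
           template("plof", consequence="splice_donor_variant"),
           Tier.PLOF_HIGH_CONFIDENCE),
        mk("G843D_like", 9e-4, AlleleClass.G843D,
           template("known_pathogenic_missense", hgvs_c="c.2528G>A",
                    hgvs_p="p.(Gly843Asp)"),
           Tier.KNOWN_PATHOGENIC),
        mk("known_missense", 5e-5, AlleleClass.MISSENSE_KNOWN,
           template("known_pathogenic_missense", clinvar="likely_pathogenic",
                    hgvs_p="p.(Arg872Trp)"),
           Tier.KNOWN_PATHOGENIC),
        mk("cryptic_splice", 3e-4, AlleleClass.PREDICTED_SPLICE,
           template("splice", spliceai=0.92),
           Tier.PREDICTED_SPLICE),
        mk("R985H_like", 4e-4, AlleleClass.PREDICTED_MISSENSE,
           template("missense", clinvar="vus", hgvs_c="c.2954G>A",
                    hgvs_p="p.(Arg985His)"),
           Tier.PREDICTED_MISSENSE),
        mk("pred_missense_3of4", 2.5e-4, AlleleClass.PREDICTED_MISSENSE,
           template("missense",
                    calls=("deleterious", "deleterious", "deleterious", "tolerated")),
           Tier.PREDICTED_MISSENSE),
        # Decoys: each fails exactly one rule.
        mk("decoy_benign", 1e-3, None, template("benign"), Tier.EXCLUDED_BENIGN),
        mk("decoy_common", 5e-3, None, template("missense"),
           Tier.EXCLUDED_FREQUENCY, hom_override=0),
        mk("decoy_hom", 1e-3, None, template("missense"),
           Tier.EXCLUDED_HOMOZYGOTE, hom_override=1),
        mk("decoy_low_spliceai", 1e-4, None, template("splice", spliceai=0.5),
           Tier.UNCLASSIFIED),
        mk("decoy_split_vote", 1e-4, None,
           template("missense",
                    calls=("deleterious", "deleterious", "tolerated", "tolerated")),
           Tier.UNCLASSIFIED),
        mk("decoy_synonymous", 2e-4, None, template("synonymous"),
           Tier.UNCLASSIFIED),
    )
    return TruthSpec(region, {"topmed_like": 600_000, "aou_like": 400_000}, planted)


def recovery_spec(
    q_total: float = 5e-3, an: int = 1_000_000, n_variants: int = 4,
    region: str = "SIM",
) -> TruthSpec:
    """Spec for parameter-recovery runs: known-pathogenic nulls only.

    The planted total allele frequency is split over ``n_variants``
    ClinVar-pathogenic LOF variants, so classification is exact and the
    recovered Q isolates binomial sampling error.
    """
    q_each = q_total / n_variants
    planted = tuple(
        PlantedVariant(
            f"null_{i}", q_each, AlleleClass.NULL,
            template("known_pathogenic_lof"), Tier.KNOWN_PATHOGENIC,
        )
        for i in range(n_variants)
    )
    return TruthSpec(region, {"simcohort": an}, planted)


def simulate_cohort(spec: TruthSpec, seed: int) -> pd.DataFrame:
    """Draw one variant annotation table from a truth spec.

    Per variant and cohort, allele_count ~ Binomial(AN, q_true) and
    hom_count ~ Binomial(floor(AN/2), q_true^2) — an independent-diploid
    approximation adequate at the rare frequencies modelled.  Returns a
    DataFrame in the classifier's TSV layout.
    """
    rows = []
    for idx, v in enumerate(spec.planted):
        rng = np.random.default_rng([int(seed), idx])
        t = v.template
        row: dict = {
            "chrom": "7",
            "pos": 92_400_000 + idx,
            "ref": "A",
            "alt": "T",
            "hgvs_c": t.get("hgvs_c", ""),
            "hgvs_p": t.get("hgvs_p", ""),
            "consequence": t["consequence"],
            "clinvar": t["clinvar"],
            "spliceai_ds_max": t.get("spliceai"),
        }
        for predictor, call in zip(MISSENSE_PREDICTORS, t["calls"]):
            row[predictor] = call
        for cohort, an in spec.cohort_an.items():
            ac = int(rng.binomial(an, v.q_true))
            if v.hom_override is None:
                hom = min(int(rng.binomial(an // 2, v.q_true**2)), ac // 2)
            else:
                hom = v.hom_override
                ac = max(ac, 2 * hom)  # keep the record invariant satisfiable
            row[f"{cohort}_AC"] = ac
            row[f"{cohort}_AN"] = an
            row[f"{cohort}_nhom"] = hom
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[variants.VariantRecord]:
    """Parse a simulated table exactly as the TSV loader would."""
    cohort_names = [c[:-3] for c in df.columns if c.endswith("_AC")]
    out = []
    for row in df.to_dict(orient="records"):
        out.append(variants._record_from_row(row, cohort_names))
    return out


def simulate_patients(
    proportions: Mapping[tuple[str, str], float], n: int, seed: int
) -> ObservedGenotypeCounts:
    """Multinomial patient cohort drawn from genotype proportions."""
    if n <= 0:
        raise ValueError("n must be positive")
    pairs = list(proportions)
    p = np.asarray([proportions[k] for k in pairs], dtype=float)
    if p.sum() <= 0:
        raise ValueError("proportions must sum to a positive value")
    p = p / p.sum()
    draws = np.random.default_rng(seed).multinomial(n, p)
    return ObservedGenotypeCounts(
        {pair: int(c) for pair, c in zip(pairs, draws)}
    )


@dataclass(frozen=True)
class RecoveryReport:
    model: str
    q_true: float
    reps: int
    mean_q_hat: float
    relative_bias: float
    ci_coverage: float
    level: float


def recovery_harness(
    spec: TruthSpec,
    reps: int,
    seed: int = 0,
    model: str = "core",
    level: float = 0.90,
    af_threshold: float = variants.DEFAULT_AF_THRESHOLD,
) -> RecoveryReport:
    """End-to-end parameter recovery on repeated simulated cohorts.

    Each replicate simulates a cohort table, runs classification and
    allele-class aggregation, and estimates the total affected-genotype
    frequency Q with its modified-Wald range; reports the relative bias of
    the mean estimate against the planted truth and the empirical CI
    coverage.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    q_true_total = spec.q_total_true(model)
    q_target = q_true_total**2
    q_hats = np.empty(reps)
    covered = 0
    for rep in range(reps):
        df = simulate_cohort(spec, seed=int(seed) + rep)
        labeled = variants.classify_table(
            records_from_frame(df), af_threshold, spec.cohorts
        )
        freqs = popgen.aggregate_allele_classes(
            labeled, spec.region, spec.cohorts, model
        )
        q_hat, ci = popgen.prevalence_ci(freqs, level)
        q_hats[rep] = q_hat
        if ci.lo <= q_target <= ci.hi:
            covered += 1
    mean_q = float(q_hats.mean())
    bias = (mean_q - q_target) / q_target if q_target > 0 else 0.0
    return RecoveryReport(
        model, q_target, reps, mean_q, float(bias), covered / reps, level
    )
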