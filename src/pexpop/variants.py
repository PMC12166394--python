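"""Variant records and the pathogenicity rule engine.

Every *PEX1* variant seen in a genetic-diversity cohort is assigned to one
tier by a fixed precedence of rules:

1. ClinVar benign / likely benign            -> ``EXCLUDED_BENIGN``
2. ClinVar pathogenic / likely pathogenic    -> ``KNOWN_PATHOGENIC``
3. essential loss-of-function consequence    -> ``PLOF_HIGH_CONFIDENCE``
4. otherwise the variant is a *candidate predicted* variant and must pass
   two filters before prediction applies:
   pooled allele frequency over the region's cohorts > threshold
                                             -> ``EXCLUDED_FREQUENCY``
   any homozygote observed in those cohorts  -> ``EXCLUDED_HOMOZYGOTE``
   SpliceAI max delta score >= 0.8           -> ``PREDICTED_SPLICE``
   missense with predictor consensus         -> ``PREDICTED_MISSENSE``
   no rule fires                             -> ``UNCLASSIFIED``

Known-pathogenic and high-confidence pLOF variants are members of both the
core and the expanded patient-population model; predicted splice and
predicted missense variants enter the expanded model only.  The allele
frequency and homozygote filters apply to predicted variants only: a
ClinVar-confirmed pathogenic variant is used regardless of its frequency.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Tier",
    "ClinVarStatus",
    "CohortCounts",
    "VariantRecord",
    "ClassLabel",
    "LoadResult",
    "ESSENTIAL_LOF_CONSEQUENCES",
    "MISSENSE_PREDICTORS",
    "DEFAULT_AF_THRESHOLD",
    "classify_variant",
    "classify_table",
    "consensus_deleterious",
    "load_variant_table",
    "write_variant_table",
]

DEFAULT_AF_THRESHOLD = 0.002
SPLICEAI_HIGH_PRECISION = 0.8

#: Consequences treated as unambiguous loss of function ("null" alleles).
ESSENTIAL_LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "start_lost",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)

#: The four in-silico missense predictors whose calls are consumed as input.
MISSENSE_PREDICTORS = ("sift", "polyphen2", "eve", "alphamissense")


class Tier(str, enum.Enum):
    KNOWN_PATHOGENIC = "KNOWN_PATHOGENIC"
    PLOF_HIGH_CONFIDENCE = "PLOF_HIGH_CONFIDENCE"
    PREDICTED_SPLICE = "PREDICTED_SPLICE"
    PREDICTED_MISSENSE = "PREDICTED_MISSENSE"
    EXCLUDED_BENIGN = "EXCLUDED_BENIGN"
    EXCLUDED_FREQUENCY = "EXCLUDED_FREQUENCY"
    EXCLUDED_HOMOZYGOTE = "EXCLUDED_HOMOZYGOTE"
    UNCLASSIFIED = "UNCLASSIFIED"


class ClinVarStatus(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    ABSENT = "absent"


# Conflicting assertions fall through to the prediction rules, same as VUS.
_CLINVAR_ALIASES: dict[str, ClinVarStatus] = {
    "pathogenic": ClinVarStatus.PATHOGENIC,
    "likely_pathogenic": ClinVarStatus.LIKELY_PATHOGENIC,
    "benign": ClinVarStatus.BENIGN,
    "likely_benign": ClinVarStatus.LIKELY_BENIGN,
    "vus": ClinVarStatus.VUS,
    "uncertain_significance": ClinVarStatus.VUS,
    "conflicting": ClinVarStatus.VUS,
    "absent": ClinVarStatus.ABSENT,
    "": ClinVarStatus.ABSENT,
    ".": ClinVarStatus.ABSENT,
}


def parse_clinvar(value: str | None) -> ClinVarStatus:
    """Map a free-text ClinVar assertion to the internal enum.

    Raises ``ValueError`` for strings outside the known vocabulary so a
    malformed table row is reported rather than silently misclassified.
    """
    if value is None:
        return ClinVarStatus.ABSENT
    key = str(value).strip().lower().replace(" ", "_")
    try:
        return _CLINVAR_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown clinvar status {value!r}") from None


@dataclass(frozen=True)
class CohortCounts:
    """Allele count / allele number / homozygote count in one cohort."""

    cohort: str
    allele_count: int
    allele_number: int
    hom_count: int = 0

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValueError(f"{self.cohort}: allele_number must be positive")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError(
                f"{self.cohort}: allele_count {self.allele_count} outside "
                f"[0, AN={self.allele_number}]"
            )
        if self.hom_count < 0 or 2 * self.hom_count > self.allele_count:
            raise ValueError(
                f"{self.cohort}: hom_count {self.hom_count} inconsistent with "
                f"AC={self.allele_count}"
            )

    @property
    def af(self) -> float:
        return self.allele_count / self.allele_number


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant with per-cohort counts — the atom of classification.

    Coordinates are GRCh38, 1-based, VCF-style minimal ref/alt.  HGVS names
    follow the NM_000466.3 transcript convention.  ``spliceai_max_delta`` is
    the maximum of the four SpliceAI delta scores, if computed.
    ``missense_calls`` holds per-predictor verdicts: ``"deleterious"``,
    ``"tolerated"`` or ``None`` (missing).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    clinvar: ClinVarStatus = ClinVarStatus.ABSENT
    hgvs_c: str = ""
    hgvs_p: str = ""
    spliceai_max_delta: float | None = None
    missense_calls: Mapping[str, str | None] = field(default_factory=dict)
    cohorts: Mapping[str, CohortCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.consequence:
            raise ValueError(f"{self.key}: missing consequence term")
        if self.spliceai_max_delta is not None and not (
            0.0 <= self.spliceai_max_delta <= 1.0
        ):
            raise ValueError(
                f"{self.key}: spliceai_max_delta {self.spliceai_max_delta} "
                "outside [0, 1]"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def pooled(self, cohort_names: Sequence[str]) -> tuple[int, int, float]:
        """Pooled (AC, AN, AF) over the named cohorts; absent cohorts count 0/0."""
        ac = an = 0
        for name in cohort_names:
            counts = self.cohorts.get(name)
            if counts is not None:
                ac += counts.allele_count
                an += counts.allele_number
        return ac, an, (ac / an if an else 0.0)

    def hom_total(self, cohort_names: Sequence[str]) -> int:
        return sum(
            self.cohorts[name].hom_count
            for name in cohort_names
            if name in self.cohorts
        )


@dataclass(frozen=True)
class ClassLabel:
    """Tier plus model membership (``core`` is always a subset of ``expanded``)."""

    tier: Tier
    membership: frozenset[str]

    @staticmethod
    def for_tier(tier: Tier) -> "ClassLabel":
        if tier in (Tier.KNOWN_PATHOGENIC, Tier.PLOF_HIGH_CONFIDENCE):
            return ClassLabel(tier, frozenset({"core", "expanded"}))
        if tier in (Tier.PREDICTED_SPLICE, Tier.PREDICTED_MISSENSE):
            return ClassLabel(tier, frozenset({"expanded"}))
        return ClassLabel(tier, frozenset())

    def in_model(self, model: str) -> bool:
        return model in self.membership


def consensus_deleterious(calls: Mapping[str, str | None]) -> bool:
    """Consensus vote over the four missense predictors.

    Deleterious iff >=3 of 4 predictors vote deleterious; with only 2 or 3
    non-missing calls, unanimity is required; fewer than 2 calls never
    reaches consensus.  This is a strict-majority reading robust to missing
    scores.
    """
    votes = [calls.get(p) for p in MISSENSE_PREDICTORS]
    available = [v for v in votes if v is not None]
    deleterious = sum(v == "deleterious" for v in available)
    n = len(available)
    if n < 2:
        return False
    if n < 4:
        return deleterious == n
    return deleterious >= 3


def classify_variant(
    v: VariantRecord,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    region_cohorts: Sequence[str] | None = None,
    lof_consequences: frozenset[str] = ESSENTIAL_LOF_CONSEQUENCES,
) -> ClassLabel:
    """Assign a single variant to its pathogenicity tier (pure function)."""
    if not 0 < af_threshold <= 1:
        raise ValueError(f"af_threshold must be in (0, 1], got {af_threshold}")
    cohorts = list(region_cohorts) if region_cohorts is not None else list(v.cohorts)

    if v.clinvar in (ClinVarStatus.BENIGN, ClinVarStatus.LIKELY_BENIGN):
        return ClassLabel.for_tier(Tier.EXCLUDED_BENIGN)
    if v.clinvar in (ClinVarStatus.PATHOGENIC, ClinVarStatus.LIKELY_PATHOGENIC):
        return ClassLabel.for_tier(Tier.KNOWN_PATHOGENIC)
    if v.consequence in lof_consequences:
        return ClassLabel.for_tier(Tier.PLOF_HIGH_CONFIDENCE)

    # Candidate predicted variant: frequency and homozygote filters first.
    _, _, af = v.pooled(cohorts)
    if af > af_threshold:
        return ClassLabel.for_tier(Tier.EXCLUDED_FREQUENCY)
    if v.hom_total(cohorts) > 0:
        return ClassLabel.for_tier(Tier.EXCLUDED_HOMOZYGOTE)
    if v.spliceai_max_delta is not None and v.spliceai_max_delta >= SPLICEAI_HIGH_PRECISION:
        return ClassLabel.for_tier(Tier.PREDICTED_SPLICE)
    if v.consequence == "missense_variant" and consensus_deleterious(v.missense_calls):
        return ClassLabel.for_tier(Tier.PREDICTED_MISSENSE)
    return ClassLabel.for_tier(Tier.UNCLASSIFIED)


def classify_table(
    records: Iterable[VariantRecord],
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    region_cohorts: Sequence[str] | None = None,
) -> list[tuple[VariantRecord, ClassLabel]]:
    return [
        (v, classify_variant(v, af_threshold, region_cohorts)) for v in records
    ]


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "clinvar",
    "spliceai_ds_max",
    "sift",
    "polyphen2",
    "eve",
    "alphamissense",
)


@dataclass
class LoadResult:
    """Parsed records plus a per-row error report (row order preserved)."""

    records: list[VariantRecord]
    errors: list[tuple[int, str]]

    def raise_on_errors(self) -> "LoadResult":
        if self.errors:
            lines = "; ".join(f"row {i}: {msg}" for i, msg in self.errors)
            raise ValueError(f"variant table had malformed rows: {lines}")
        return self


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", ".", "nan", "NA"):
        return None
    return float(s)


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value).strip()
    return "" if s in (".", "nan", "NA") else s


def _opt_call(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", ".", "nan", "na"):
        return None
    if s not in ("deleterious", "tolerated"):
        raise ValueError(f"unknown predictor call {value!r}")
    return s


def _cohort_names_from_columns(columns: Sequence[str]) -> list[str]:
    names = []
    for col in columns:
        if col.endswith("_AC"):
            base = col[:-3]
            if f"{base}_AN" in columns:
                names.append(base)
    if not names:
        raise ValueError(
            "no cohort columns found (expected {cohort}_AC/{cohort}_AN pairs)"
        )
    return names


def _record_from_row(row: Mapping, cohort_names: Sequence[str]) -> VariantRecord:
    cohorts = {}
    for name in cohort_names:
        an = row.get(f"{name}_AN")
        if an is None or (isinstance(an, float) and pd.isna(an)):
            continue
        an = int(an)
        if an == 0:
            raise ValueError(f"cohort {name}: AN=0")
        ac = int(row.get(f"{name}_AC", 0) or 0)
        nhom = int(row.get(f"{name}_nhom", 0) or 0)
        cohorts[name] = CohortCounts(name, ac, an, nhom)
    pos = int(row["pos"])
    if pos <= 0:
        raise ValueError(f"non-positive position {pos}")
    return VariantRecord(
        chrom=str(row["chrom"]),
        pos=pos,
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        hgvs_c=_opt_str(row.get("hgvs_c")),
        hgvs_p=_opt_str(row.get("hgvs_p")),
        consequence=_opt_str(row.get("consequence")),
        clinvar=parse_clinvar(row.get("clinvar")),
        spliceai_max_delta=_opt_float(row.get("spliceai_ds_max")),
        missense_calls={p: _opt_call(row.get(p)) for p in MISSENSE_PREDICTORS},
        cohorts=cohorts,
    )


def load_variant_table(path: str | Path, dialect: str = "tsv") -> LoadResult:
    """Read a variant annotation table (TSV or VCF dialect).

    Malformed rows (bad coordinates, negative counts, AC > AN, AN = 0,
    unknown ClinVar vocabulary, missing consequence) are skipped and listed
    in the returned error report; well-formed rows keep their input order.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        rows = df.to_dict(orient="records")
        cohort_names = _cohort_names_from_columns(list(df.columns))
    elif dialect == "vcf":
        rows, cohort_names = _rows_from_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    records: list[VariantRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(rows):
        try:
            records.append(_record_from_row(row, cohort_names))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append((i, str(exc)))
    return LoadResult(records, errors)


def _rows_from_vcf(path: Path) -> tuple[list[dict], list[str]]:
    import pysam

    rows: list[dict] = []
    cohort_names: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for key in vcf.header.info:
            if key.endswith("_AC") and f"{key[:-3]}_AN" in vcf.header.info:
                cohort_names.append(key[:-3])
        for rec in vcf:
            info = dict(rec.info)
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "",
            }
            for name in _FIXED_COLUMNS[4:]:
                value = info.get(name)
                if isinstance(value, tuple):
                    value = value[0]
                if name == "spliceai_ds_max" and value is not None:
                    # htslib stores INFO floats in single precision
                    value = round(float(value), 6)
                row[name] = value
            for cohort in cohort_names:
                for suffix, key in (("_AC", "_AC"), ("_AN", "_AN"), ("_nhom", "_NHOM")):
                    value = info.get(f"{cohort}{key}")
                    if isinstance(value, tuple):
                        value = value[0]
                    row[f"{cohort}{suffix}"] = value
            rows.append(row)
    return rows, cohort_names


def write_variant_table(
    df: pd.DataFrame, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a variant annotation table in the TSV or VCF 4.2 dialect.

    ``df`` uses the TSV column layout (fixed annotation columns followed by
    ``{cohort}_AC/_AN/_nhom`` triples).
    """
    path = Path(path)
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")

    cohort_names = _cohort_names_from_columns(list(df.columns))
    str_fields = [c for c in _FIXED_COLUMNS[4:] if c != "spliceai_ds_max"]
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(df["chrom"].astype(str)):
        lines.append(f"##contig=<ID={chrom}>")
    for name in str_fields:
        lines.append(
            f'##INFO=<ID={name},Number=1,Type=String,Description="{name}">'
        )
    lines.append(
        '##INFO=<ID=spliceai_ds_max,Number=1,Type=Float,Description="max SpliceAI delta">'
    )
    for cohort in cohort_names:
        for suffix, typ in (("AC", "Integer"), ("AN", "Integer"), ("NHOM", "Integer")):
            lines.append(
                f'##INFO=<ID={cohort}_{suffix},Number=1,Type={typ},'
                f'Description="{cohort} {suffix}">'
            )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for _, row in df.iterrows():
        info_parts = []
        for name in str_fields + ["spliceai_ds_max"]:
            value = row.get(name)
            if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
                continue
            info_parts.append(f"{name}={value}")
        for cohort in cohort_names:
            for suffix, key in (("AC", "_AC"), ("AN", "_AN"), ("NHOM", "_nhom")):
                value = row.get(f"{cohort}{key}")
                if value is None or (isinstance(value, float) and pd.isna(value)):
                    continue
                info_parts.append(f"{cohort}_{suffix}={int(value)}")
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
            f"\t.\t.\t{';'.join(info_parts)}"
        )
    path.write_text("\n".join(lines) + "\n")
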