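"""Pathogenicity rule engine and variant-table IO."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pexpop import simulate
from pexpop.variants import (
    ESSENTIAL_LOF_CONSEQUENCES,
    CohortCounts,
    Tier,
    VariantRecord,
    classify_variant,
    consensus_deleterious,
    load_variant_table,
    parse_clinvar,
    write_variant_table,
)

ALL4 = dict(zip(("sift", "polyphen2", "eve", "alphamissense"), ["deleterious"] * 4))


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "kwargs, tier, membership",
        [
            # ClinVar-pathogenic missense above the AF threshold stays in:
            # the frequency filter applies to predicted variants only.
            (
                dict(consequence="missense_variant", clinvar="pathogenic", af=0.0024),
                Tier.KNOWN_PATHOGENIC,
                {"core", "expanded"},
            ),
            (
                dict(consequence="stop_gained", af=1e-5),
                Tier.PLOF_HIGH_CONFIDENCE,
                {"core", "expanded"},
            ),
            (
                dict(consequence="missense_variant", calls=ALL4, af=0.005),
                Tier.EXCLUDED_FREQUENCY,
                set(),
            ),
            (
                dict(consequence="intron_variant", spliceai=0.85, af=1e-4),
                Tier.PREDICTED_SPLICE,
                {"expanded"},
            ),
            (
                dict(consequence="synonymous_variant"),
                Tier.UNCLASSIFIED,
                set(),
            ),
            (
                dict(consequence="missense_variant", clinvar="benign", calls=ALL4),
                Tier.EXCLUDED_BENIGN,
                set(),
            ),
            (
                dict(consequence="missense_variant", calls=ALL4, af=1e-4, hom=2),
                Tier.EXCLUDED_HOMOZYGOTE,
                set(),
            ),
            (
                dict(consequence="missense_variant", calls=ALL4, af=1e-4),
                Tier.PREDICTED_MISSENSE,
                {"expanded"},
            ),
            # SpliceAI exactly at the 0.8 high-precision cutoff is included.
            (
                dict(consequence="missense_variant", spliceai=0.8, af=1e-4),
                Tier.PREDICTED_SPLICE,
                {"expanded"},
            ),
            # ClinVar VUS falls through to prediction (R985H-style route).
            (
                dict(
                    consequence="missense_variant",
                    clinvar="vus",
                    calls=ALL4,
                    af=1e-4,
                    hgvs_p="p.(Arg985His)",
                ),
                Tier.PREDICTED_MISSENSE,
                {"expanded"},
            ),
        ],
    )
    def test_tier_and_membership(self, make_variant, kwargs, tier, membership):
        label = classify_variant(make_variant(**kwargs), 0.002, ["pop"])
        assert label.tier == tier
        assert set(label.membership) == membership

    def test_every_lof_consequence_is_plof(self, make_variant):
        for consequence in ESSENTIAL_LOF_CONSEQUENCES:
            label = classify_variant(make_variant(consequence=consequence))
            assert label.tier == Tier.PLOF_HIGH_CONFIDENCE

    def test_pure_function(self, make_variant):
        v = make_variant(consequence="stop_gained")
        assert classify_variant(v, 0.002, ["pop"]) == classify_variant(
            v, 0.002, ["pop"]
        )

    def test_core_membership_subset_of_expanded(self, labeled):
        core = {r.key for r, l in labeled if l.in_model("core")}
        expanded = {r.key for r, l in labeled if l.in_model("expanded")}
        assert core and core < expanded

    def test_tiers_partition_table(self, labeled):
        # every record gets exactly one tier by construction; check totality
        assert all(isinstance(l.tier, Tier) for _, l in labeled)

    @given(
        af=st.floats(1e-6, 0.02),
        thr_lo=st.floats(1e-4, 0.01),
        thr_hi=st.floats(1e-4, 0.01),
    )
    @settings(max_examples=60, derandomize=True)
    def test_threshold_monotonicity(self, af, thr_lo, thr_hi):
        """Lowering the AF threshold never rescues an excluded variant."""
        thr_lo, thr_hi = sorted((thr_lo, thr_hi))
        v = VariantRecord(
            chrom="7",
            pos=1,
            ref="A",
            alt="T",
            consequence="missense_variant",
            missense_calls=ALL4,
            cohorts={"pop": CohortCounts("pop", round(af * 10**6), 10**6)},
        )
        tier_lo = classify_variant(v, thr_lo, ["pop"]).tier
        tier_hi = classify_variant(v, thr_hi, ["pop"]).tier
        if tier_hi == Tier.EXCLUDED_FREQUENCY:
            assert tier_lo == Tier.EXCLUDED_FREQUENCY

    def test_missing_consequence_rejected(self):
        with pytest.raises(ValueError, match="consequence"):
            VariantRecord(chrom="7", pos=1, ref="A", alt="T", consequence="")

    def test_unknown_clinvar_rejected(self):
        with pytest.raises(ValueError, match="clinvar"):
            parse_clinvar("probably_fine")


class TestConsensusVote:
    @pytest.mark.parametrize(
        "votes, expected",
        [
            (["deleterious"] * 4, True),
            (["deleterious"] * 3 + ["tolerated"], True),
            (["deleterious"] * 2 + ["tolerated"] * 2, False),
            (["deleterious"] * 3 + [None], True),  # 3 available, unanimous
            (["deleterious", "deleterious", "tolerated", None], False),
            (["deleterious", "deleterious", None, None], True),  # 2, unanimous
            (["deleterious", None, None, None], False),  # too few calls
            ([None] * 4, False),
            (["tolerated"] * 4, False),
        ],
    )
    def test_rule(self, votes, expected):
        calls = dict(zip(("sift", "polyphen2", "eve", "alphamissense"), votes))
        assert consensus_deleterious(calls) is expected


class TestTableIO:
    def _frame(self):
        return pd.DataFrame(
            [
                {
                    "chrom": "7",
                    "pos": 92503172,
                    "ref": "C",
                    "alt": "CT",
                    "hgvs_c": "c.2097dup",
                    "hgvs_p": "p.(Ile700fs*42)",
                    "consequence": "frameshift_variant",
                    "clinvar": "pathogenic",
                    "spliceai_ds_max": None,
                    "sift": None,
                    "polyphen2": None,
                    "eve": None,
                    "alphamissense": None,
                    "cohortA_AC": 12,
                    "cohortA_AN": 50000,
                    "cohortA_nhom": 0,
                },
                {
                    "chrom": "7",
                    "pos": 92494369,
                    "ref": "C",
                    "alt": "T",
                    "hgvs_c": "c.2954G>A",
                    "hgvs_p": "p.(Arg985His)",
                    "consequence": "missense_variant",
                    "clinvar": "vus",
                    "spliceai_ds_max": 0.05,
                    "sift": "deleterious",
                    "polyphen2": "deleterious",
                    "eve": "deleterious",
                    "alphamissense": "deleterious",
                    "cohortA_AC": 30,
                    "cohortA_AN": 50000,
                    "cohortA_nhom": 0,
                },
                {
                    "chrom": "7",
                    "pos": 92501562,
                    "ref": "C",
                    "alt": "T",
                    "hgvs_c": "c.2528G>A",
                    "hgvs_p": "p.(Gly843Asp)",
                    "consequence": "missense_variant",
                    "clinvar": "pathogenic",
                    "spliceai_ds_max": None,
                    "sift": "deleterious",
                    "polyphen2": "deleterious",
                    "eve": None,
                    "alphamissense": "deleterious",
                    "cohortA_AC": 44,
                    "cohortA_AN": 50000,
                    "cohortA_nhom": 0,
                },
            ]
        )

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "variants.tsv"
        write_variant_table(self._frame(), path)
        loaded = load_variant_table(path)
        assert not loaded.errors
        assert [r.pos for r in loaded.records] == [92503172, 92494369, 92501562]
        r985h = loaded.records[1]
        assert r985h.missense_calls["eve"] == "deleterious"
        assert r985h.spliceai_max_delta == pytest.approx(0.05)
        assert r985h.cohorts["cohortA"].allele_count == 30

    def test_vcf_dialect_matches_tsv(self, tmp_path):
        """TSV -> VCF -> records reproduces the TSV-parsed records."""
        df = self._frame()
        tsv, vcf = tmp_path / "v.tsv", tmp_path / "v.vcf"
        write_variant_table(df, tsv)
        write_variant_table(df, vcf, dialect="vcf")
        from_tsv = load_variant_table(tsv).raise_on_errors().records
        from_vcf = load_variant_table(vcf, dialect="vcf").raise_on_errors().records
        assert from_vcf == from_tsv

    def test_malformed_rows_reported_and_skipped(self, tmp_path):
        df = self._frame()
        df.loc[1, "cohortA_AC"] = 70000  # AC > AN violates the record invariant
        path = tmp_path / "bad.tsv"
        write_variant_table(df, path)
        loaded = load_variant_table(path)
        assert len(loaded.records) == 2
        assert [i for i, _ in loaded.errors] == [1]
        with pytest.raises(ValueError, match="row 1"):
            loaded.raise_on_errors()

    def test_comment_lines_ignored(self, tmp_path):
        path = tmp_path / "commented.tsv"
        write_variant_table(self._frame(), path)
        content = path.read_text()
        path.write_text("# provenance comment\n" + content)
        assert len(load_variant_table(path).records) == 3

    def test_simulated_table_round_trips_through_tsv(self, paper_spec, cohort_df, tmp_path):
        path = tmp_path / "sim.tsv"
        write_variant_table(cohort_df, path)
        loaded = load_variant_table(path).raise_on_errors()
        assert loaded.records == simulate.records_from_frame(cohort_df)
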