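import pytest

from pexpop import simulate, variants
from pexpop.variants import CohortCounts, VariantRecord


@pytest.fixture(scope="session")
def paper_spec():
    """US-like synthetic truth spec shared by pipeline-level tests."""
    return simulate.paper_like_spec()


@pytest.fixture(scope="session")
def cohort_df(paper_spec):
    return simulate.simulate_cohort(paper_spec, seed=7)


@pytest.fixture(scope="session")
def labeled(paper_spec, cohort_df):
    records = simulate.records_from_frame(cohort_df)
    return variants.classify_table(records, 0.002, paper_spec.cohorts)


@pytest.fixture
def make_variant():
    """Factory for single-cohort variant records with sensible defaults."""

    def _make(
        consequence="missense_variant",
        clinvar="absent",
        af=1e-4,
        an=1_000_000,
        hom=0,
        spliceai=None,
        calls=None,
        hgvs_p="",
        pos=92_500_000,
    ):
        ac = round(af * an)
        calls = calls or {}
        return VariantRecord(
            chrom="7",
            pos=pos,
            ref="A",
            alt="T",
            consequence=consequence,
            clinvar=variants.parse_clinvar(clinvar),
            hgvs_p=hgvs_p,
            spliceai_max_delta=spliceai,
            missense_calls=dict(calls),
            cohorts={"pop": CohortCounts("pop", ac, an, hom)},
        )

    return _make
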