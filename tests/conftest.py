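import pytest

from polyqprofile.fixtures import (
    build_ancestry_fixture,
    build_results_fixtures,
    build_table1_fixture,
)


@pytest.fixture(scope="session")
def table1():
    """(records, annotations, ld_by_gene) for the 38-row association fixture."""
    return build_table1_fixture()


@pytest.fixture(scope="session")
def results():
    """(215-record catalog, 10-gene profiles, 12 OMIM entries)."""
    return build_results_fixtures()


@pytest.fixture(scope="session")
def ancestry_records():
    return build_ancestry_fixture()


def make_record(**kwargs):
    """An AssociationRecord with sensible defaults for unit tests."""
    from polyqprofile.types import AssociationRecord

    defaults = dict(
        gene_symbol="G1",
        gene_id="ENSG00000000001",
        trait_label="trait one",
        trait_category="measurement",
        study_id="S1",
        pubmed_id="12345",
        source="GWAS_catalog",
        l2g=0.8,
        variant_id="rs1",
        chrom="1",
        pos=100,
        gwas_p=1e-9,
        ancestries=frozenset({"EUR"}),
    )
    defaults.update(kwargs)
    return AssociationRecord(**defaults)
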