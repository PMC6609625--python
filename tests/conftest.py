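import pytest

from milkatlas import fixtures
from milkatlas.crossref import EvidenceTable
from milkatlas.idmap import IdMappingTable


@pytest.fixture(scope="session")
def early_table():
    return fixtures.early_lactation_table()


@pytest.fixture(scope="session")
def early_genes(early_table):
    return early_table["gene_name"].tolist()


@pytest.fixture(scope="session")
def fraction_sets():
    return fixtures.fraction_localization_sets()


@pytest.fixture(scope="session")
def name_annotations():
    return fixtures.protein_name_annotations()


@pytest.fixture(scope="session")
def evidence_table():
    return EvidenceTable.from_tsv(fixtures.candidate_evidence_path())


@pytest.fixture()
def small_mapping():
    return IdMappingTable.from_pairs(
        [("P62803", "HIST1H4A"), ("Q95M55", "LF")], source_tag="test")
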