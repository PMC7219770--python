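import pytest

from codonpairing.seqio_genetics import GeneRecord, GeneticCode


@pytest.fixture(scope="session")
def code():
    return GeneticCode.from_table_id(1)


def make_gene(codons, species_id="sp", ortholog_key="g"):
    """Build a GeneRecord directly from a codon list (no stop appended)."""
    return GeneRecord(species_id=species_id, ortholog_key=ortholog_key, cds="".join(codons))


@pytest.fixture
def gene_factory():
    return make_gene
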