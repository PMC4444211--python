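import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    from mitoplasmy import default_reference

    return default_reference()


@pytest.fixture(scope="session")
def genes():
    from mitoplasmy import load_gene_model

    return load_gene_model()


@pytest.fixture(scope="session")
def genes_by_name(genes):
    return {g.name: g for g in genes}


@pytest.fixture(scope="session")
def region_map(genes):
    from mitoplasmy import default_region_map

    return default_region_map(genes)


@pytest.fixture(scope="session")
def locus_table():
    from mitoplasmy import load_locus_table

    return load_locus_table()


@pytest.fixture(scope="session")
def novel_rare_table():
    from mitoplasmy import load_novel_rare_table

    return load_novel_rare_table()


@pytest.fixture(scope="session")
def repeat_loci(ref):
    from mitoplasmy import default_repeat_loci

    return default_repeat_loci(ref)
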