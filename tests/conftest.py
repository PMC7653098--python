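import pytest

from mitopair.classify import classify_cohort
from mitopair.haplogroups import load_panel
from mitopair.reference import GeneticCode, load_gene_map
from mitopair.simulate import generate_cohort
from mitopair.summary import CohortTable


@pytest.fixture(scope="session")
def gene_map():
    return load_gene_map()


@pytest.fixture(scope="session")
def code():
    return GeneticCode.vertebrate_mitochondrial()


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def default_cohort(gene_map, code):
    """One default-sized synthetic cohort, classified and annotated."""
    records, metadata, truth = generate_cohort(seed=11, gene_map=gene_map)
    classified = classify_cohort(records, gene_map=gene_map, genetic_code=code)
    cohort = CohortTable(patients=metadata, records=classified)
    return {
        "records": records,
        "metadata": metadata,
        "truth": truth,
        "classified": classified,
        "cohort": cohort,
    }
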