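import pytest

from nucsurvey.alignment import AlignmentParams, SubstitutionMatrix
from nucsurvey.search import SearchEngine
from nucsurvey.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture(scope="session")
def params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def engine():
    """One shared search engine; its cache is keyed by accession so tests
    must use unique genome accessions or a fresh engine."""
    return SearchEngine()


def tiny_config(**overrides) -> SyntheticConfig:
    """A one-phylum, 12-genome configuration for fast pipeline tests."""
    base = dict(
        seed=7,
        n_phyla=1,
        classes_per_phylum=1,
        orders_per_class=1,
        families_per_order=1,
        genera_per_family=2,
        species_per_genus=2,
        genomes_per_species=3,
        background_length=6000,
        plasmid_length=3000,
        plasmid_fraction=0.3,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(tiny_config())
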