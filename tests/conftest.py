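import pytest

from dgetag.reference import UnigeneRecord, extract_reference_tags
from dgetag.simulate import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """Study-shaped configuration scaled down for fast tests."""
    base = dict(
        n_genes=300,
        gene_length_mean=600.0,
        gene_length_sd=120.0,
        library_size=30_000,
        singleton_noise=500,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def toy_unigenes():
    """Five hand-written unigenes; G1 and G2 share one 21-mer window."""
    shared = "CATG" + "ACGTACGTACGTACGTA"  # identical window in G1 and G2
    return [
        UnigeneRecord("G1", shared + "TTTTTTTTTT"),
        UnigeneRecord("G2", "GGGGG" + shared),
        UnigeneRecord("G3", "CATG" + "C" * 17),
        UnigeneRecord("G4", "CATGCATG" + "A" * 17),
        UnigeneRecord("G5", "TTTTAAAACCCCGGGGTTTTAAAA"),  # no CATG
    ]


@pytest.fixture(scope="session")
def toy_reference(toy_unigenes):
    return extract_reference_tags(toy_unigenes)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared six-library simulation reused across read-only tests."""
    return simulate_dataset(small_config(seed=7))
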