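import numpy as np
import pytest

from svforge.genome import HaplotypeSet, ReferenceGenome, generate_synthetic_reference


@pytest.fixture(scope="session")
def small_reference() -> ReferenceGenome:
    """A two-chromosome 50 kb synthetic reference shared across tests."""
    return generate_synthetic_reference(
        {"chr1": 30_000, "chr2": 20_000}, gc_target=0.45, seed=101
    )


@pytest.fixture(scope="session")
def megabase_reference() -> ReferenceGenome:
    """A 1 Mb single-chromosome reference for read-level tests."""
    return generate_synthetic_reference({"chr1": 1_000_000}, gc_target=0.41, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def haploid_megabase(megabase_reference) -> HaplotypeSet:
    return HaplotypeSet(
        [("chr1", 0, megabase_reference.chromosomes["chr1"])], genome_id="fix"
    )
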