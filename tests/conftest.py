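import numpy as np
import pytest

from sgcseq import ErrorMatrix, SimulationSpec, simulate_reference


@pytest.fixture
def rng():
    return np.random.default_rng(20110630)


@pytest.fixture
def uniform_p():
    """Uniform 1% miscall error matrix."""
    return ErrorMatrix.uniform(0.01)


@pytest.fixture(scope="session")
def fixture_reference():
    """Small synthetic reference with planted sites, SNPs and repeats."""
    spec = SimulationSpec(
        seed=7,
        genome_length=15_000,
        site_spacing={"GATC": 300, "TTAA": 450},
        n_snps=15,
        n_exons=8,
        genes=3,
        n_repeats=1,
        repeat_length=200,
        repeat_copies=2,
    )
    return simulate_reference(spec)


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
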