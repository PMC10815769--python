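import numpy as np
import pytest

from sexscreen import synthetic


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def small_spec() -> synthetic.SexGenomeSpec:
    """A miniature ZW genome: 40 kb autosome, 6 kb gametolog, two W-unique
    insertions, four trap loci."""
    return synthetic.build_genome_spec(
        system="ZW",
        autosome_length=40_000,
        sex_shared_length=6_000,
        unique_lengths=(800, 1_200),
        n_traps=4,
        trap_length=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_population(small_spec):
    return synthetic.simulate_population(
        small_spec, n_females=3, n_males=3, pool_size=8, seed=11
    )
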