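import numpy as np
import pytest

from cubkit.genetic_code import ALL_CODONS
from cubkit.genome_io import CodonCounts
from cubkit.synthetic_data import SyntheticGenomeSpec, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """200 genes, mild selection and coupling — a quick all-purpose input."""
    spec = SyntheticGenomeSpec(
        n_genes=200, length_median_codons=200, coupling_k=0.5,
        selection_strength=0.5, seed=5,
    )
    return simulate_genome(spec)


def random_counts(rng: np.random.Generator, n_codons: int = 300) -> CodonCounts:
    """A random 64-slot count table with Dirichlet-multinomial codon usage."""
    probs = rng.dirichlet(np.ones(len(ALL_CODONS)))
    draws = rng.multinomial(n_codons, probs)
    return CodonCounts.from_mapping(dict(zip(ALL_CODONS, draws.tolist())))
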