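import numpy as np
import pytest

from famtag.types import GeneticMap, GenotypeMatrix, MaternalLD, Parent, ParentalHaplotypes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_map():
    """Five markers spread over 2 cM on one chromosome."""
    return GeneticMap(
        marker_id=[f"m{i}" for i in range(1, 6)],
        chromosome=["1"] * 5,
        position_cm=np.array([0.0, 0.5, 1.0, 1.5, 2.0]),
    )


@pytest.fixture
def het_sire(small_map):
    """One sire heterozygous everywhere, coupling phase throughout."""
    hap = np.vstack([np.ones(5, dtype=int), np.zeros(5, dtype=int)])
    return ParentalHaplotypes(
        parents=[Parent(family="F1", role="sire", haplotypes=hap)],
        family_size={"F1": 100},
    )


@pytest.fixture
def flat_maternal(small_map):
    """Maternal population at frequency 0.5 everywhere, no LD."""
    p = np.full(5, 0.5)
    return MaternalLD(D=np.diag(p * (1 - p)), p_freq=p)


def random_genotypes(rng, n=40, p=8, missing_rate=0.0, families=("A", "B")):
    vals = rng.integers(0, 3, size=(n, p))
    if missing_rate:
        vals[rng.random((n, p)) < missing_rate] = -1
    fam = [families[i % len(families)] for i in range(n)]
    return GenotypeMatrix(
        values=vals,
        family_label=fam,
        marker_ids=[f"m{j}" for j in range(p)],
        individual_ids=[f"i{i}" for i in range(n)],
    )


@pytest.fixture
def genotype_factory():
    return random_genotypes
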