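import numpy as np
import pytest

from sirescan import builtin_codon_sets, make_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return make_table1_fixture()


@pytest.fixture(scope="session")
def sets():
    return builtin_codon_sets()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220309)


def random_column(rng, n_min=12, n_max=60):
    """A codon column mixing set members, arbitrary codons and gaps.

    Concentrates on one focal codon set so the 10-instance rule is often
    met with segregation, while still exercising foreign codons, other
    sets and gap codons.
    """
    from sirescan.codon_sets import builtin_codon_sets

    all_sets = builtin_codon_sets()
    pool = sorted({c for s in all_sets for c in s.codons})
    focal = sorted(all_sets[int(rng.integers(len(all_sets)))].codons)
    bases = "ACGT"
    n = int(rng.integers(n_min, n_max + 1))
    column = []
    for _ in range(n):
        r = rng.random()
        if r < 0.70:
            column.append(focal[int(rng.integers(len(focal)))])
        elif r < 0.85:
            column.append(pool[int(rng.integers(len(pool)))])
        elif r < 0.95:
            column.append("".join(bases[int(rng.integers(4))]
                                  for _ in range(3)))
        else:
            column.append("---")
    return column
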