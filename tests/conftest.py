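import numpy as np
import pytest

from ssrkit import simulate
from ssrkit.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def fixtures():
    return simulate.fixture_library()


@pytest.fixture(scope="session")
def tiny6(fixtures):
    return fixtures["tiny6"]


@pytest.fixture(scope="session")
def threepools(fixtures):
    return fixtures["threepools"]


@pytest.fixture(scope="session")
def clonebank(fixtures):
    return fixtures["clonebank"]


def random_matrix(
    n: int, L: int, seed: int, alleles: int = 6, missing_rate: float = 0.0
) -> GenotypeMatrix:
    """Small random genotype matrix for property tests."""
    rng = np.random.default_rng(seed)
    calls = []
    ladder = [100 + 2 * k for k in range(alleles)]
    for i in range(n):
        row = []
        for j in range(L):
            if rng.random() < missing_rate:
                row.append(None)
            else:
                a, b = rng.choice(ladder, size=2, replace=True)
                row.append((int(min(a, b)), int(max(a, b))))
        calls.append(row)
    return GenotypeMatrix.from_calls(
        [f"A{i:03d}" for i in range(n)],
        [f"L{j:02d}" for j in range(L)],
        calls,
    )
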