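import numpy as np
import pytest

from kbac.data import GenotypeMatrix, PhenotypeTable


@pytest.fixture
def worked_example():
    """4 cases / 4 controls; pattern (1,0) in two cases, (0,1) in one control.

    Hand-derived expectations: hypergeometric weights 1.0 for the case-only
    pattern and 0.5 for the control singleton; one-sided S = 0.375,
    two-sided 0.140625.
    """
    dos = np.array([[1, 0], [1, 0], [0, 0], [0, 0],
                    [0, 1], [0, 0], [0, 0], [0, 0]])
    gm = GenotypeMatrix(dosages=dos, site_ids=["a", "b"])
    ph = PhenotypeTable(status=[1, 1, 1, 1, 0, 0, 0, 0])
    return gm, ph


@pytest.fixture(scope="session")
def small_neutral_pools():
    """Neutral constant-size pools for sampling-level tests (cheap)."""
    from kbac.popgen import DemographyModel, SelectionModel, generate_pool_set

    dem = DemographyModel(epochs=[(80, 1)], burn_in=800)
    return generate_pool_set(4, dem, SelectionModel.neutral(),
                             mu=0.004, L=1, seed=123)


def random_tally(rng, max_sites=4, max_patterns=6, N=40):
    """Random valid PatternTally for property tests."""
    from kbac.data import PatternTally

    k = rng.integers(1, max_patterns + 1)
    pats = set()
    while len(pats) < k:
        v = tuple(rng.integers(0, 3, size=max_sites))
        if any(v):
            pats.add(v)
    patterns = np.array(sorted(pats))
    NA = int(rng.integers(5, N - 5))
    n = rng.multinomial(N // 2, np.ones(k + 1) / (k + 1))[:k] + 1
    while n.sum() > N - 2:
        n[np.argmax(n)] -= 1
    n0 = N - int(n.sum())
    # draw case counts by a random label assignment
    labels = np.zeros(N, dtype=int)
    labels[:NA] = 1
    labels = rng.permutation(labels)
    bounds = np.concatenate([[0], np.cumsum(np.append(n, n0))])
    nA = np.array([labels[bounds[i]:bounds[i + 1]].sum() for i in range(k)])
    nA0 = int(labels[bounds[k]:].sum())
    return PatternTally(patterns=patterns, n=n, nA=nA, nU=n - nA,
                        n0=n0, nA0=nA0, nU0=n0 - nA0, N=N, NA=NA, NU=N - NA)
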