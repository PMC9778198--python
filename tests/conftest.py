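import numpy as np
import pytest

from ssrcore import GenotypeMatrix, PopulationMap
from ssrcore.simulate import SimulationConfig, simulate_dataset, study_scale_dataset


def make_gm(genotypes, locus_ids=None, entry_ids=None):
    """Build a GenotypeMatrix from nested [[ (a,b) per locus ] per entry] lists."""
    n = len(genotypes)
    L = len(genotypes[0])
    entry_ids = entry_ids or [f"E{i + 1}" for i in range(n)]
    locus_ids = locus_ids or [f"L{l + 1}" for l in range(L)]
    calls = np.empty((n, L, 2), dtype=object)
    for i, row in enumerate(genotypes):
        for l, pair in enumerate(row):
            calls[i, l, 0], calls[i, l, 1] = pair
    return GenotypeMatrix(entry_ids, locus_ids, calls)


@pytest.fixture(scope="session")
def study_dataset():
    """Study-scale dataset: 232 entries, 17 provenances, 32 loci, F=0.042."""
    return study_scale_dataset(seed=1)


@pytest.fixture(scope="session")
def two_pop_divergent():
    """Two well-separated populations (F=0.3) for structure recovery tests."""
    cfg = SimulationConfig(
        pop_sizes=(40, 40), n_loci=32, fst_target=0.3, missing_rate=0.02, seed=7
    )
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_gm():
    """Four individuals, one biallelic locus: (A,A),(A,B),(B,B),(A,A)."""
    return make_gm([[("A", "A")], [("A", "B")], [("B", "B")], [("A", "A")]])


@pytest.fixture
def pm_two_pops():
    return PopulationMap({"E1": "p1", "E2": "p1", "E3": "p2", "E4": "p2"})
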