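import numpy as np
import pytest

from hicscaf import (Assembly, Contig, PairTable, RunConfig, SimParams,
                     simulate_benchmark)

# desk-scale ladder suited to 1 Mb chromosomes
DESK_LADDER = (10_000, 20_000, 50_000, 100_000, 200_000)

DESK_PARAMS = SimParams(seed=1)


@pytest.fixture(scope="session")
def desk_config():
    return RunConfig(resolutions=DESK_LADDER)


@pytest.fixture(scope="session")
def sim_error_free():
    """Full desk-scale error-free benchmark (20 x 1 Mb, 2e6 pairs)."""
    return simulate_benchmark(DESK_PARAMS)


@pytest.fixture(scope="session")
def sim_errored():
    """Sibling benchmark with the 10/10/5 misjoin scheme (30 junctions)."""
    return simulate_benchmark(DESK_PARAMS, (10, 10, 5))


@pytest.fixture(scope="session")
def small_sim():
    """Quick 3 x 200 kb benchmark for unit-level end-to-end checks."""
    params = SimParams(n_chromosomes=3, chrom_length=200_000, contig_min=10_000,
                       contig_max=30_000, n_pairs=100_000, seed=7)
    return params, simulate_benchmark(params)


@pytest.fixture
def toy_assembly():
    return Assembly([
        Contig("c1", 300, "ACGT" * 75),
        Contig("c2", 200, "TTGCA" * 40),
        Contig("c3", 450, "GATTACA" * 64 + "GA"),
    ])


def random_pair_table(names, lengths, n, seed):
    rng = np.random.default_rng(seed)
    cid1 = rng.integers(0, len(names), n)
    cid2 = rng.integers(0, len(names), n)
    lens = np.array([lengths[nm] for nm in names])
    pos1 = (rng.random(n) * lens[cid1]).astype(np.int64)
    pos2 = (rng.random(n) * lens[cid2]).astype(np.int64)
    return PairTable(names, cid1, pos1, cid2, pos2)
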