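import numpy as np
import pytest

from peppermap import SimConfig, make_f2_truth, simulate_f2, simulate_reference
from peppermap.mapping import inverse_kosambi


@pytest.fixture(scope="session")
def small_reference():
    return simulate_reference(n_chrom=2, chrom_len=50_000, n_genes=20, seed=7)


def simulate_marker_pair(r, n, rng):
    """Two F2 marker genotype vectors with true recombination fraction r."""
    g1a = (rng.random(n) < 0.5).astype(np.int8)
    g1b = (rng.random(n) < 0.5).astype(np.int8)
    g2a = g1a ^ (rng.random(n) < r)
    g2b = g1b ^ (rng.random(n) < r)
    return (g1a + g1b).astype(np.int8), (g2a + g2b).astype(np.int8)


def simulate_chromosome_codes(positions_cM, n_f2, rng):
    """F2 genotype codes for ordered markers at the given cM positions."""
    m = len(positions_cM)
    r = inverse_kosambi(np.diff(np.asarray(positions_cM, dtype=float)))
    start = rng.random((2 * n_f2, 1)) < 0.5
    sw = rng.random((2 * n_f2, m - 1)) < r
    al = np.cumsum(np.hstack([start, sw]).astype(np.int8), axis=1) % 2
    return (al[:n_f2] + al[n_f2:]).astype(np.int8)


@pytest.fixture(scope="session")
def two_chromosome_f2():
    """An F2 of 200 individuals over two 80 cM chromosomes, 15 markers each."""
    truth = make_f2_truth(n_chrom=2, markers_per_chrom=15, chrom_cM=80.0,
                          seed=21)
    cfg = SimConfig(seed=22, n_f2=200, missing_rate=0.0)
    return truth, simulate_f2(truth, 200, cfg)
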