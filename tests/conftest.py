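import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # bruteforce oracles

from triobin import kmer_core, sim_trio, trio_binning


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trio():
    """100 kb parents at 0.5% divergence with 1%-error long reads."""
    config = sim_trio.TrioSimConfig(
        genome_length=100_000,
        long_read_mean=8_000.0,
        long_read_coverage=8.0,
        long_read_error=0.01,
        seed=77,
    )
    hap_a, hap_b, variants = sim_trio.simulate_parents(config)
    reads, truth = sim_trio.simulate_f1_long_reads(hap_a, hap_b, config)
    return config, hap_a, hap_b, variants, reads, truth


@pytest.fixture(scope="session")
def small_trio_markers(small_trio):
    """Homopentamer-filtered parent-unique 21-mer markers of the small trio."""
    _, hap_a, hap_b, _, _, _ = small_trio
    spec = kmer_core.KmerSpec(21)
    ta = kmer_core.count_kmers([hap_a], spec, "parent_a")
    tb = kmer_core.count_kmers([hap_b], spec, "parent_b")
    ma, mb = trio_binning.derive_unique_markers(ta, tb, min_count=1)
    return (
        trio_binning.filter_homopolymer_markers(ma),
        trio_binning.filter_homopolymer_markers(mb),
    )
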