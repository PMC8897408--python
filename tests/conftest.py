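import numpy as np
import pytest

import museopop as mp
from museopop.simulate import BASE_CODE


@pytest.fixture(scope="session")
def two_pop_config():
    """Two populations, modest split, small panel: fast shared simulation."""
    return mp.SpeciesTreeConfig(
        labels=("A", "B"),
        merges=(mp.PopulationMerge(80_000.0, "B", "A"),),
        ne=5_000.0, samples={"A": 3, "B": 3},
        n_windows=20, seed=11,
    )


@pytest.fixture(scope="session")
def two_pop_sim(two_pop_config):
    return mp.simulate_genealogies(two_pop_config)


@pytest.fixture(scope="session")
def two_pop_panel(two_pop_sim):
    return mp.mutate_sequences(two_pop_sim)


def make_pileup(counts, qual=30.0, contigs=None, positions=None,
                individuals=None):
    """PileupSet from a raw (S, N, 4) count array."""
    counts = np.asarray(counts, dtype=np.uint16)
    S, N, _ = counts.shape
    if contigs is None:
        contigs = ["chr1"]
        contig_idx = np.zeros(S, dtype=np.int32)
    else:
        contigs, contig_idx = contigs
    if positions is None:
        positions = np.arange(1, S + 1, dtype=np.int64)
    if individuals is None:
        individuals = [f"ind{i:02d}" for i in range(N)]
    return mp.PileupSet(contigs=contigs, contig_idx=contig_idx,
                        pos=np.asarray(positions, dtype=np.int64),
                        counts=counts, individuals=individuals, qual=qual)


def counts_from_bases(base_counts):
    """dict like {'A': 10, 'C': 5} -> length-4 count vector."""
    out = np.zeros(4, dtype=np.uint16)
    for b, n in base_counts.items():
        out[BASE_CODE[b]] = n
    return out
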