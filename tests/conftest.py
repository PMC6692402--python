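import numpy as np
import pandas as pd
import pytest

from chialoop import GenomeLayout, GeneTable, LoopSet, PeakSet, SimulationConfig
from chialoop.simulate import simulate_dataset


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout(("chr1", "chr2"), (5_000_000, 5_000_000))


@pytest.fixture(scope="session")
def sim_data():
    """One full synthetic dataset (seed 1, default study conditions)."""
    cfg = SimulationConfig(seed=1)
    keys = ("layout", "peaks", "loops", "genes", "expr", "eqtl", "truth")
    return dict(zip(keys, simulate_dataset(cfg)))


def random_peaks(rng, n, mark="H3K4me3", chroms=("chr1", "chr2"),
                 max_pos=100_000):
    rows = []
    for i in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, max_pos))
        e = s + int(rng.integers(100, 3000))
        rows.append((c, s, e, float(rng.uniform(0, 10)), f"p{i}"))
    return PeakSet(mark, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "intensity", "name"]))


def random_loops(rng, n, mark="H3K4me3", chroms=("chr1", "chr2"),
                 max_pos=100_000):
    rows = []
    for i in range(n):
        c = chroms[rng.integers(len(chroms))]
        s1 = int(rng.integers(0, max_pos))
        e1 = s1 + int(rng.integers(100, 2000))
        s2 = int(rng.integers(0, max_pos))
        e2 = s2 + int(rng.integers(100, 2000))
        rows.append((c, s1, e1, c, s2, e2, f"L{i}",
                     int(rng.integers(1, 10)), 0.01))
    return LoopSet(mark, pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                       "end2", "id", "pet_count", "fdr"]))


def random_genes(rng, n, chroms=("chr1", "chr2"), max_pos=100_000):
    rows = []
    for i in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, max_pos))
        e = s + int(rng.integers(500, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"g{i}", c, s, e, strand, "unknown", False))
    return GeneTable(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "category", "is_te"]))
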