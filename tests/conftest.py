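import numpy as np
import pandas as pd
import pytest

from methdesert.intervals import partition_genome


@pytest.fixture
def small_grid():
    """Ten 100 kb windows over two chromosomes."""
    return partition_genome({"chrA": 600_000, "chrB": 400_000}, window_size=100_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, chrom_sizes, n, min_len=50, max_len=5000):
    chroms = list(chrom_sizes)
    rows = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(min_len, max_len))
        s = int(rng.integers(0, chrom_sizes[c] - length))
        rows.append((c, s, s + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
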