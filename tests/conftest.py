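import numpy as np
import pandas as pd
import pytest

import methmotif as mm


@pytest.fixture
def tiny_genome():
    return mm.Genome({"chr1": "TTGCAACGTTGGCCAT"})


@pytest.fixture
def random_genome():
    """100 kb iid genome at human-like composition."""
    return mm.simulate_genome(mm.GenomeSpec(length=100_000, seed=314))


def make_records(rows):
    """Build a cytosine table from (contig, pos, strand, meth, unmeth, context)."""
    return pd.DataFrame(rows, columns=mm.meth_io.REPORT_COLUMNS)


@pytest.fixture
def planted_gc_data():
    """Small genome with a planted GC methylome, shared across tests."""
    genome = mm.simulate_genome(mm.GenomeSpec(length=100_000, seed=21))
    records, truth = mm.simulate_methylome(
        genome,
        [mm.MTaseSpec("GC", efficiency=0.9)],
        coverage=mm.CoverageSpec(mean_depth=20, seed=22),
    )
    return genome, records, truth
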