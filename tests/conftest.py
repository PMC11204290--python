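import numpy as np
import pytest

from epiloop.core import (
    GenomicInterval,
    SampleDescriptor,
    SignalTable,
    TranscriptionUnit,
    UnitSet,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240626)


@pytest.fixture
def toy_units():
    """Three non-overlapping units on one chromosome, mixed strands."""
    return UnitSet(
        [
            TranscriptionUnit(GenomicInterval("Chr1", 100, 600, "+"), "g1"),
            TranscriptionUnit(GenomicInterval("Chr1", 1000, 1500, "-"), "g2"),
            TranscriptionUnit(GenomicInterval("Chr1", 2000, 2300, "+"), "g3", "te_gene"),
        ]
    )


def make_table(values, genotypes=("WT",), assay="H3K36me3", n_reps=None, kind="rpkm"):
    """Build a SignalTable from a dense array; columns cycle genotype x rep."""
    values = np.asarray(values, dtype=float)
    n_units, n_cols = values.shape
    if n_reps is None:
        n_reps = n_cols // len(genotypes)
    samples = [
        SampleDescriptor(g, assay, rep)
        for g in genotypes
        for rep in range(1, n_reps + 1)
    ]
    units = [f"g{i + 1}" for i in range(n_units)]
    return SignalTable(units, samples, values, kind)
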