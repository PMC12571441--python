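import numpy as np
import pandas as pd
import pytest

from ecidentity import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    SimulationConfig,
)


@pytest.fixture
def tiny_genes():
    return [
        GeneModel("geneA", "chr1", 100_000, 105_000, "+"),
        GeneModel("geneB", "chr1", 200_000, 203_000, "-"),
        GeneModel("geneC", "chr1", 300_000, 310_000, "+"),
    ]


@pytest.fixture
def small_matrix():
    """4 genes x 3 cells with a clear per-cell ordering."""
    values = pd.DataFrame(
        {
            "c1": [10.0, 5.0, 2.0, 0.0],
            "c2": [0.0, 1.0, 8.0, 3.0],
            "c3": [4.0, 4.0, 4.0, 4.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def mini_sim_config():
    """A small-genome configuration for fast end-to-end runs."""
    return SimulationConfig(
        seed=0,
        n_genes=30,
        chrom_length=1_000_000,
        gene_length_range=(1000, 2000),
        min_gene_spacing=25_000,
        n_identity_genes=5,
        broad_domain_span=(3000, 3000),
        n_target_genes=10,
        n_cells=90,
        signature_set_size=8,
    )


def make_peak(chrom, start, end, score=1.0, summit=None):
    return Peak(GenomicInterval(chrom, start, end), score, summit)
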