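import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from transgen_meth.methylome import GeneModel, MethylMatrix


@pytest.fixture
def tiny_matrix():
    """4 CpGs x 4 samples (Addict/Non-addict in F0 and F1), hand-written counts."""
    sites = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [100, 200, 300, 400]})
    samples = pd.DataFrame(
        {
            "sample_id": ["A0", "N0", "A1", "N1"],
            "generation": ["F0", "F0", "F1", "F1"],
            "phenotype": ["Addict", "Non-addict", "Addict", "Non-addict"],
        }
    )
    meth = np.array(
        [
            [9, 1, 9, 1],    # strong Addict-high difference in both generations
            [1, 9, 1, 9],    # strong Addict-low difference in both generations
            [5, 5, 5, 5],    # no difference
            [9, 1, 1, 9],    # difference flips direction between generations
        ]
    )
    total = np.full((4, 4), 10)
    return MethylMatrix(sites, meth, total, samples)


@pytest.fixture
def two_gene_model():
    """Two genes on chr1: plus-strand at 10k-20k and minus-strand at 50k-60k."""
    return GeneModel(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "-"],
                "start": [10_000, 50_000],
                "end": [20_000, 60_000],
                "exon_starts": [[10_000, 15_000], [50_000, 58_000]],
                "exon_ends": [[12_000, 16_000], [52_000, 60_000]],
            }
        )
    )
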