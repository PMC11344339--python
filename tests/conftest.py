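import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from foundersplice.gene_model import TranscriptModel


@pytest.fixture
def toy_plus_model():
    """Two exons of 100 nt at genomic 1001 and 2001, CDS = whole transcript."""
    return TranscriptModel("TOY+", "chr1", "+", ((1001, 1100), (2001, 2100)),
                           1, 198, check_cds_frame=False)


@pytest.fixture
def toy_minus_model():
    """Minus strand: two exons, transcription order genomically decreasing."""
    return TranscriptModel("TOY-", "chr1", "-", ((2001, 2100), (1001, 1100)),
                           1, 198, check_cds_frame=False)


def make_model_with_exon_ends(tx_ends, strand="+", chrom="chrT"):
    """Build a model whose cumulative exon ends (tx coordinates) are as given."""
    lens = np.diff([0] + list(tx_ends))
    exons, g = [], 10_000
    for ln in lens:
        exons.append((g, g + int(ln) - 1))
        g += int(ln) + 500
    if strand == "-":
        total = exons[-1][1] + 1000
        exons = [(total - b, total - a) for a, b in exons]
    return TranscriptModel("BOUND", chrom, strand, tuple(exons), 1, int(tx_ends[-1]),
                           check_cds_frame=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
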