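import numpy as np
import pytest

from mtable.annotation import GeneModel, Region, derive_all_regions
from mtable.methio import CONTEXTS, CytosineRecord


@pytest.fixture
def toy_genes():
    return [
        GeneModel("g1", "chr1", 1000, 2000, "+", symbol="ALPHA"),
        GeneModel("g2", "chr1", 5000, 7000, "-", symbol="BETA"),
        GeneModel("g3", "chr2", 100, 400, "+"),
    ]


@pytest.fixture
def toy_regions(toy_genes):
    return derive_all_regions(toy_genes, promoter_length=500)


def random_records(rng, n, chroms=("chr1", "chr2"), max_pos=8000):
    """Small random cytosine record lists for property-style tests."""
    records = []
    for _ in range(n):
        records.append(
            CytosineRecord(
                chrom=str(rng.choice(list(chroms))),
                pos=int(rng.integers(0, max_pos)),
                strand="+" if rng.integers(2) == 0 else "-",
                meth=int(rng.integers(0, 20)),
                unmeth=int(rng.integers(0, 20)),
                context=str(rng.choice(list(CONTEXTS))),
            )
        )
    return records


def random_regions(rng, genes=("g1", "g2", "g3"), chroms=("chr1", "chr2"),
                   max_pos=8000):
    regions = []
    for gene in genes:
        chrom = str(rng.choice(list(chroms)))
        for kind in ("promoter", "body"):
            start = int(rng.integers(0, max_pos - 1))
            end = int(rng.integers(start + 1, max_pos + 1))
            regions.append(Region(chrom, start, end, kind, gene))
    return regions


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
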