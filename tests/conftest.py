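import numpy as np
import pytest

from ploidymeth.genome import GeneModel, GenomeAnnotation, ReadSet
from ploidymeth.simulate import SimulationConfig


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Handmade two-gene annotation on a 20 kb chromosome."""
    genes = [
        GeneModel("gA", "chr1", "+", 5000, 8000,
                  exons=((5000, 6000), (7000, 8000)),
                  utr5=((5000, 5100),), utr3=((7900, 8000),)),
        GeneModel("gB", "chr1", "-", 12000, 15000,
                  exons=((12000, 15000),),
                  utr5=((14900, 15000),), utr3=((12000, 12100),)),
    ]
    return GenomeAnnotation({"chr1": 20000}, genes)


@pytest.fixture
def small_config() -> SimulationConfig:
    """Fast simulation: 60 genes on one 400 kb chromosome."""
    return SimulationConfig(
        seed=11, n_chromosomes=1, chromosome_length=400_000, n_genes=60,
        n_diff_genes=6,
        depth_per_ploidy={"1N": 60_000, "2N": 120_000, "3N": 180_000},
        n_expression_diff=10,
    )


def make_readset(sample: str, chrom: str, starts, read_length: int = 50) -> ReadSet:
    s = np.asarray(starts, dtype=np.int64)
    return ReadSet(sample=sample, starts={chrom: s.copy()},
                   ends={chrom: s + read_length})
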