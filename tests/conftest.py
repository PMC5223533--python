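import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from telandscape.core import ChromosomeSpec, GeneModel, GenomicInterval
from telandscape.compartments import build_compartment_map
from telandscape.simulate import SyntheticSpec, simulate_dataset


@pytest.fixture
def single_exon_gene():
    """One gene [5000, 8000) fully exonic on a 20-kb chromosome."""
    gene = GeneModel(
        "gA",
        GenomicInterval("chr1", 5000, 8000, "+"),
        (GenomicInterval("chr1", 5000, 8000, "+"),),
    )
    chroms = [ChromosomeSpec("chr1", 20000)]
    return gene, chroms


@pytest.fixture
def single_gene_cmap(single_exon_gene):
    gene, chroms = single_exon_gene
    return build_compartment_map([gene], chroms, flank_bp=2000)


@pytest.fixture
def two_exon_gene():
    """Same span but exons [5000,6000) and [7000,8000): 1-kb intron."""
    gene = GeneModel(
        "gA",
        GenomicInterval("chr1", 5000, 8000, "+"),
        (
            GenomicInterval("chr1", 5000, 6000, "+"),
            GenomicInterval("chr1", 7000, 8000, "+"),
        ),
    )
    chroms = [ChromosomeSpec("chr1", 20000)]
    return gene, chroms


@pytest.fixture(scope="session")
def neutral_dataset():
    """Mid-size neutral (delta=1, beta=1) synthetic dataset, shared read-only."""
    spec = SyntheticSpec(
        seed=11, n_chroms=2, chrom_length=400_000, n_genes=80, n_tes=800
    )
    return simulate_dataset(spec)
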