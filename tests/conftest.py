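import numpy as np
import pytest

from barseqkit import barcodes as bc_mod
from barseqkit import constructs, simdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def library(rng):
    """Seven-strain library: three barcoded wild-type controls, four mutants."""
    names = ["WT-1", "WT-2", "WT-3", "dGeneA", "dGeneB", "dGeneC", "dGeneD"]
    return bc_mod.build_library(names, rng, min_distance=3)


@pytest.fixture
def amplicons(library):
    return {
        name: simdata.build_amplicon(
            constructs.assemble_bar_scar(bc), i5="ACGTACGT", i7="TGCATGCA"
        )
        for name, bc in library.items()
    }


def make_gene(rng, length: int) -> str:
    """A syntactically valid ORF: ATG + stop-free body + TAA."""
    assert length % 3 == 0 and length >= 9
    codons = [c for c in bc_mod.VNN_CODONS]
    body = "".join(
        codons[i] for i in rng.integers(0, len(codons), size=length // 3 - 2)
    )
    return "ATG" + body + "TAA"


@pytest.fixture
def toy_genome(rng):
    """10-kb replicon with a real 900-nt ORF on the plus strand at [4000, 4900)."""
    bases = "ACGT"
    flank5 = "".join(bases[i] for i in rng.integers(0, 4, size=4000))
    flank3 = "".join(bases[i] for i in rng.integers(0, 4, size=5100))
    gene = make_gene(rng, 900)
    genome = {"chr1": flank5 + gene + flank3}
    target = constructs.GeneTarget("chr1", 4000, 4900, "+", "geneX")
    return genome, target
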