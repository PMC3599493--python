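import numpy as np
import pytest

from tdmrscan import GeneModel, GenomeAssembly, MethylomeProfile
from tdmrscan.synthetic import generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 20-gene genome reused by read-only tests (generation is seeded)."""
    return generate_genome(n_genes=20, cgi_fraction=0.5, seed=11)


@pytest.fixture()
def single_site_contig():
    """100-bp contig with one HpyCH4IV site at 40 and no TaqI site."""
    seq = "A" * 40 + "ACGT" + "A" * 56
    genome = GenomeAssembly({"chr1": seq})

    def methylome(m: float) -> MethylomeProfile:
        return MethylomeProfile("s", {"chr1": {41: m}})

    return genome, methylome


def make_gene(gene_id="g0", contig="chr1", tss=10000, strand="+"):
    return GeneModel(gene_id=gene_id, contig=contig, tss=tss, strand=strand)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
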