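import numpy as np
import pytest

from fusionwire import fixtures
from fusionwire.gene_models import GeneModel, GenomicInterval


@pytest.fixture(scope="session")
def toy_genes():
    return fixtures.load_toy_gene_models()


@pytest.fixture(scope="session")
def preset_fusions(toy_genes):
    return fixtures.all_preset_fusions(toy_genes)


@pytest.fixture(scope="session")
def cohort_fusions(preset_fusions):
    return {
        grp: (preset_fusions[name] if name else None)
        for grp, name in fixtures.GROUP_FUSIONS.items()
    }


def make_gene(gene_id="G", n_exons=9, strand="+", chrom="chrT", offset=0):
    """Toy gene: exon k spans [offset + 1000k, offset + 1000k + 200)."""
    ivs = [
        GenomicInterval(chrom, offset + 1000 * k, offset + 1000 * k + 200, strand)
        for k in range(1, n_exons + 1)
    ]
    return GeneModel.from_intervals(gene_id, strand, ivs)


@pytest.fixture
def nine_exon_gene():
    return make_gene()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
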