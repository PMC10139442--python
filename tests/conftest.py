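import numpy as np
import pytest

from texpress.models import GeneModel, TEAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_gene(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    cds=((3000, 3200), (3800, 4000)),
    chrom_length=None,
):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_intervals=tuple(cds),
        chrom_length=chrom_length,
    )


def make_te(te_id="te1", chrom="chr1", start=0, end=100, te_type="DNA"):
    return TEAnnotation(
        te_id=te_id, chrom=chrom, start=start, end=end, te_type=te_type
    )
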