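import pytest

from intramir.annotation_io import GeneModel, GenomicInterval, MirnaLocus


def make_gene(
    gene_id="G1",
    symbol=None,
    chrom="chr1",
    strand="+",
    exons=((100, 200), (300, 400), (500, 600)),
    cds=None,
):
    """Compact gene-model factory for hand-built fixtures."""
    exon_ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol or gene_id,
        interval=GenomicInterval(chrom, exons[0][0], exons[-1][1], strand),
        exons=exon_ivs,
        cds_start=cds[0] if cds else None,
        cds_end=cds[1] if cds else None,
    )


def make_mirna(mirna_id="m1", chrom="chr1", start=250, end=270, strand="+"):
    return MirnaLocus(mirna_id, GenomicInterval(chrom, start, end, strand))


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle shared across the session."""
    from intramir.synthetic_data import SyntheticConfig, generate

    return generate(SyntheticConfig(seed=7))
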