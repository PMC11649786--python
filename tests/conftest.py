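import pytest

from epimeta.annotation import TranscriptModel, build_metagene_model
from epimeta.simulate import GeneratorConfig, make_genome_annotation


@pytest.fixture
def toy_plus():
    """3-exon plus-strand transcript; UTR5/CDS/UTR3 partition the exons."""
    return TranscriptModel(
        gene_id="G1", transcript_id="G1.t1", chrom="chr1", strand="+",
        exons=[(1000, 1200), (1500, 1800), (2100, 2400)],
        utr5=[(1000, 1150)],
        cds=[(1150, 1200), (1500, 1800), (2100, 2250)],
        utr3=[(2250, 2400)],
    )


@pytest.fixture
def toy_minus():
    """Same genomic structure on the minus strand (5' end at the right)."""
    return TranscriptModel(
        gene_id="G2", transcript_id="G2.t1", chrom="chr1", strand="-",
        exons=[(1000, 1200), (1500, 1800), (2100, 2400)],
        utr5=[(2250, 2400)],
        cds=[(1150, 1200), (1500, 1800), (2100, 2250)],
        utr3=[(1000, 1150)],
    )


@pytest.fixture
def mg_default():
    return build_metagene_model()


@pytest.fixture(scope="session")
def sim_default():
    """Session-wide toy genome: 120 genes on two chromosomes."""
    cfg = GeneratorConfig(seed=11, n_genes=120)
    return cfg, make_genome_annotation(cfg)
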