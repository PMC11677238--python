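import pytest

from mitoreg.genome_io import GeneRecord, GenomeAnnotation, GeneSet, Peak, PeakSet


@pytest.fixture
def small_annotation() -> GenomeAnnotation:
    """Five genes on two chromosomes, both strands, TSSs well separated."""
    return GenomeAnnotation(
        [
            GeneRecord("gA", "chr1", "+", 5000, 8000),
            GeneRecord("gB", "chr1", "-", 15000, 18000),
            GeneRecord("gC", "chr1", "+", 25000, 26000),
            GeneRecord("gD", "chr2", "-", 5000, 9000),
            GeneRecord("gE", "chr2", "+", 20000, 24000),
        ]
    )


@pytest.fixture
def mito_set() -> GeneSet:
    return GeneSet(name="mito", genes=frozenset({"gA", "gB", "gD"}), subgroups={"gA": "Mito-EBR"})


def make_peakset(tf, triples, **kwargs):
    return PeakSet(
        tf_name=tf,
        peaks=[Peak(chrom=c, start=s, end=e, name=f"{tf}_{i}", **kwargs) for i, (c, s, e) in enumerate(triples)],
    )
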