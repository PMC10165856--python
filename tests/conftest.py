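import numpy as np
import pytest

import haschseq as hs

SESSION_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle shared by the read-only tests."""
    return hs.simulate_dataset(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return hs.run_pipeline(bundle, seed=SESSION_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_gene(gene_id="g1", chromosome="chr1", strand="+", start=10_000, length=2_000,
              utr=150, intron=(700, 1300)):
    """A simple two-exon gene with UTRs at the transcript ends."""
    end = start + length
    tss = start if strand == "+" else end - 1
    tts = end - 1 if strand == "+" else start
    exons = [(start, start + intron[0]), (start + intron[1], end)]
    if strand == "+":
        utr5, utr3 = [(start, start + utr)], [(end - utr, end)]
    else:
        utr5, utr3 = [(end - utr, end)], [(start, start + utr)]
    return hs.GeneModel(gene_id=gene_id, chromosome=chromosome, strand=strand,
                        tss=tss, tts=tts, exons=exons, utr5=utr5, utr3=utr3)


def make_snp(sid="s1", chrom="chr1", pos=100, ip1=30, ip2=30, in1=30, in2=30,
             a1="A", a2="G", flank1=None, flank2=None):
    return hs.SnpRecord(
        id=sid,
        coord_hap1=hs.GenomeCoordinate("hap1", chrom, pos),
        coord_hap2=hs.GenomeCoordinate("hap2", chrom, pos),
        allele_hap1=a1, allele_hap2=a2,
        ip_count_hap1=ip1, ip_count_hap2=ip2,
        input_count_hap1=in1, input_count_hap2=in2,
        flank_hap1=flank1, flank_hap2=flank2)
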