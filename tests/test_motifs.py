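import numpy as np
import pytest
from scipy import stats

from haschseq.motifs import (
    BZR1_MOTIFS,
    CONTROL_MOTIFS,
    IUPAC,
    MotifSet,
    canonical_bias_fraction,
    match_starts,
    positional_motif_profile,
    reverse_complement,
    scan_asb_motif_variants,
)

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def test_reverse_complements_are_generated():
    ms = MotifSet("G-box", ["CACGTG"])
    assert ms.patterns == ["CACGTG"]                 # palindrome: no duplicate
    brre = MotifSet("BRRE", ["CGTGYG"])
    assert "CRCACG" in brre.patterns                 # rc of CGTG[CT]G


def test_brre_destroyed_by_central_snp_is_canonical_on_high():
    #            0123456789A  (center = index 5)
    high = "AATTCGTGTGA"       # BRRE CGTGTG starting at offset 4, covers center
    low = "AATTCTTGTGA"        # central G->T kills it
    (call,) = [c for c in scan_asb_motif_variants([("s", high, low)], [MotifSet("BRRE", ["CGTGYG"])])]
    assert call.classification == "canonical-on-high"
    assert call.allele_with_motif == "high"


def test_motif_not_covering_snp_is_uninformative():
    # G-box present on both alleles away from the centre base (13-mers,
    # centre index 6): a match not spanning the SNP cannot be altered by it
    high = "CACGTGAAAAAAA"
    low = "CACGTGGAAAAAA"
    (call,) = scan_asb_motif_variants([("s", high, low)], [MotifSet("G-box", ["CACGTG"])])
    assert call.classification == "uninformative"


def test_indel_fragments_are_uninformative():
    calls = scan_asb_motif_variants([("s", "ACGTACGTACG", "ACGTACG")], BZR1_MOTIFS)
    assert all(c.classification == "uninformative" for c in calls)


def test_strand_symmetry_of_classification(rng):
    frags = [("s%d" % i, random_seq(rng, 11), random_seq(rng, 11)) for i in range(300)]
    fwd = scan_asb_motif_variants(frags, BZR1_MOTIFS + CONTROL_MOTIFS)
    rev = scan_asb_motif_variants(
        [(i, reverse_complement(h), reverse_complement(l)) for i, h, l in frags],
        BZR1_MOTIFS + CONTROL_MOTIFS)
    assert [(c.snp_id, c.motif_name, c.classification) for c in fwd] == \
           [(c.snp_id, c.motif_name, c.classification) for c in rev]


def iupac_match_oracle(seq, pattern, start):
    if start < 0 or start + len(pattern) > len(seq):
        return False
    for a, b in zip(seq[start:start + len(pattern)], pattern):
        if a not in IUPAC[b]:
            return False
    return True


def test_scan_matches_sliding_window_oracle(rng):
    """Motif-presence calls equal a brute-force oracle on 1,000 fragments."""
    ms = MotifSet("BRRE", ["CGTGYG", "CRCACG"])
    frags = [(f"s{i}", random_seq(rng, 11), random_seq(rng, 11)) for i in range(1000)]
    calls = {c.snp_id: c for c in scan_asb_motif_variants(frags, [ms])}
    for sid, high, low in frags:
        def covered(seq):
            return any(iupac_match_oracle(seq, p, st)
                       for p in ms.patterns
                       for st in range(len(seq))
                       if st <= 5 < st + len(p))
        h, l = covered(high), covered(low)
        expected = ("canonical-on-high" if h and not l
                    else "canonical-on-low" if l and not h
                    else "uninformative")
        assert calls[sid].classification == expected


def test_positional_profile_single_match():
    flank = 10
    seq = list("A" * 21)
    seq[7:13] = "CGTGTG"       # starts 3 left of the centre (index 10)
    prof = positional_motif_profile(["".join(seq)], MotifSet("BRRE", ["CGTGYG"]), flank=flank)
    assert prof[flank - 3] == 1
    assert prof.sum() == 1


def test_planted_central_enrichment_peaks_at_center(bundle, pipeline_result):
    """Motif starts on the high-affinity allele cluster within 6 bp of ASBs."""
    calls = pipeline_result.asb.calls
    seqs = []
    for c in calls:
        high = c.snp.flank_hap1 if c.direction == "hap1" else c.snp.flank_hap2
        if high:
            seqs.append(high)
    flank = len(seqs[0]) // 2
    prof = positional_motif_profile(seqs, BZR1_MOTIFS[0], flank=flank) + \
        positional_motif_profile(seqs, BZR1_MOTIFS[1], flank=flank)
    center = slice(flank - 6, flank + 7)
    assert prof[center].sum() >= 0.5 * prof.sum()
    assert prof[center].max() == prof.max()


def test_uniformly_planted_control_is_flat(rng):
    """A control motif planted uniformly leaves no positional structure."""
    flank, n = 50, 2000
    width = 2 * flank + 1
    seqs = []
    for _ in range(n):
        s = list(random_seq(rng, width))
        start = int(rng.integers(0, width - 5))   # any start where a 6-mer fits
        s[start:start + 6] = "GTACGG"
        seqs.append("".join(s))
    prof = positional_motif_profile(seqs, MotifSet("SBP-box", ["GTACGG"],
                                                  add_reverse_complements=False),
                                    flank=flank)
    valid = prof[: width - 5]                  # starts where a 6-mer fits
    chi, p = stats.chisquare(valid)
    assert p > 0.01


def test_canonical_bias_fraction_examples_and_recovery(rng):
    calls = scan_asb_motif_variants(
        [(f"s{i}", "AATTCGTGTGA", "AATTCTTGTGA") for i in range(10)],
        [MotifSet("BRRE", ["CGTGYG"])])
    res = canonical_bias_fraction(calls)
    assert res["fraction"] == 1.0
    assert res["p_value"] == pytest.approx(2 * 0.5**10, rel=1e-9)

    half = calls[:5] + scan_asb_motif_variants(
        [(f"t{i}", "AATTCTTGTGA", "AATTCGTGTGA") for i in range(5)],
        [MotifSet("BRRE", ["CGTGYG"])])
    res = canonical_bias_fraction(half)
    assert res["fraction"] == 0.5
    assert res["p_value"] == pytest.approx(1.0)

    # planted true fraction 0.9 at n=500: estimate within 3 binomial SEs
    k = int(rng.binomial(500, 0.9))
    mixed = scan_asb_motif_variants(
        [(f"h{i}", "AATTCGTGTGA", "AATTCTTGTGA") for i in range(k)]
        + [(f"l{i}", "AATTCTTGTGA", "AATTCGTGTGA") for i in range(500 - k)],
        [MotifSet("BRRE", ["CGTGYG"])])
    res = canonical_bias_fraction(mixed)
    assert abs(res["fraction"] - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / 500)
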