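"""IUPAC motif scanning around ASBs.

Detects SNPs that create or destroy a canonical TF-binding motif by
comparing the two allelic flank sequences, and builds positional
motif-start profiles on the higher-affinity allele.  Canonical BZR1
motifs are the brassinosteroid response element (BRRE, CGTG[CT]G and its
reverse complement C[GA]CACG) and the G-box (CACGTG); GCC-box and SBP-box
serve as GC-matched controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .asb import binomial_bias_test
from .errors import ConfigError, InputError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class MotifSet:
    """A named set of IUPAC patterns; reverse complements are added
    automatically unless already listed."""

    name: str
    patterns: list[str]
    add_reverse_complements: bool = True

    def __post_init__(self) -> None:
        pats = []
        for p in self.patterns:
            p = p.upper()
            if any(b not in IUPAC for b in p):
                raise ConfigError(f"motif set {self.name}: invalid IUPAC pattern {p!r}")
            pats.append(p)
        if self.add_reverse_complements:
            for p in list(pats):
                rc = reverse_complement(p)
                if rc not in pats:
                    pats.append(rc)
        self.patterns = pats


#: the default motif sets used throughout
BZR1_MOTIFS = [
    MotifSet("BRRE", ["CGTGYG", "CRCACG"]),
    MotifSet("G-box", ["CACGTG"]),
]
CONTROL_MOTIFS = [
    MotifSet("GCC-box", ["GCCGCC"]),
    MotifSet("SBP-box", ["GTACGG", "CCGTAC"]),
]


def matches_at(seq: str, pattern: str, start: int) -> bool:
    """Whether ``pattern`` matches ``seq`` starting at ``start`` (forward)."""
    if start < 0 or start + len(pattern) > len(seq):
        return False
    return all(seq[start + i] in IUPAC[p] for i, p in enumerate(pattern))


def match_starts(seq: str, pattern: str) -> list[int]:
    """All forward-strand start offsets where ``pattern`` matches ``seq``."""
    L = len(pattern)
    return [i for i in range(len(seq) - L + 1) if matches_at(seq, pattern, i)]


@dataclass
class MotifCall:
    snp_id: str
    motif_name: str
    allele_with_motif: str        # "high", "low", "both", "neither"
    classification: str           # "canonical-on-high", "canonical-on-low", "uninformative"


def _covers_center(seq: str, patterns: Sequence[str], center: int) -> bool:
    """Whether any pattern match overlaps the central SNP base."""
    for p in patterns:
        L = len(p)
        for start in range(max(0, center - L + 1), min(center, len(seq) - L) + 1):
            if matches_at(seq, p, start):
                return True
    return False


def scan_asb_motif_variants(
    fragments: Iterable[tuple[str, str, str]],
    motif_sets: Optional[Sequence[MotifSet]] = None,
) -> list[MotifCall]:
    """Classify SNPs by motif presence on the high- vs low-affinity allele.

    ``fragments`` yields (snp_id, high_allele_seq, low_allele_seq); both
    sequences are odd-length flanks centred on the SNP base (the typical
    width is 11 bp).  A motif counts only when its match window contains
    the central base — a match elsewhere cannot be altered by the SNP.
    Sequences of unequal length (indels within the fragment) make the SNP
    uninformative.
    """
    motif_sets = list(motif_sets) if motif_sets is not None else list(BZR1_MOTIFS)
    calls: list[MotifCall] = []
    for snp_id, high, low in fragments:
        for ms in motif_sets:
            if high is None or low is None or len(high) != len(low) or len(high) % 2 == 0:
                calls.append(MotifCall(snp_id, ms.name, "neither", "uninformative"))
                continue
            center = len(high) // 2
            on_high = _covers_center(high.upper(), ms.patterns, center)
            on_low = _covers_center(low.upper(), ms.patterns, center)
            if on_high and not on_low:
                calls.append(MotifCall(snp_id, ms.name, "high", "canonical-on-high"))
            elif on_low and not on_high:
                calls.append(MotifCall(snp_id, ms.name, "low", "canonical-on-low"))
            elif on_high and on_low:
                calls.append(MotifCall(snp_id, ms.name, "both", "uninformative"))
            else:
                calls.append(MotifCall(snp_id, ms.name, "neither", "uninformative"))
    return calls


def positional_motif_profile(
    sequences: Iterable[str],
    motif_set: MotifSet,
    flank: int = 100,
) -> np.ndarray:
    """Counts of motif-match starts per offset relative to the centre base.

    Sequences must have length ``2*flank + 1``; offsets run from ``-flank``
    to ``+flank`` (index ``offset + flank`` in the returned array).  Both
    strands are covered through the reverse-complement patterns of the set.
    """
    width = 2 * flank + 1
    counts = np.zeros(width, dtype=int)
    for seq in sequences:
        if len(seq) != width:
            raise InputError(f"sequence length {len(seq)} != {width} for flank={flank}")
        seq = seq.upper()
        for p in motif_set.patterns:
            for start in match_starts(seq, p):
                counts[start] += 1
    return counts


def canonical_bias_fraction(calls: Sequence[MotifCall]) -> dict:
    """Fraction of informative motif calls where the canonical motif sits
    on the higher-affinity allele, with an exact two-sided test vs 0.5."""
    informative = [c for c in calls if c.classification != "uninformative"]
    n = len(informative)
    k = sum(1 for c in informative if c.classification == "canonical-on-high")
    if n == 0:
        return {"n_informative": 0, "n_canonical_on_high": 0,
                "fraction": float("nan"), "p_value": float("nan")}
    return {
        "n_informative": n,
        "n_canonical_on_high": k,
        "fraction": k / n,
        "p_value": binomial_bias_test(k, n, 0.5),
    }
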