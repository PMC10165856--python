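"""Genomic feature classification and target-gene assignment.

Every position gets exactly one of the eight feature classes
(:data:`haschseq.models.LOCATION_CLASSES`).  When several genes' windows
contain a position the class of highest priority wins
(exon > intron > UTR > 1 kb upstream > 1 kb downstream > 1-5 kb upstream),
with ties at equal priority broken by nearest TSS.  Upstream/downstream
windows are strand-oriented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .models import CLASS_PRIORITY, GeneModel


@dataclass
class FeatureAssignment:
    snp_id: str
    location_class: str
    gene_id: Optional[str]                  # None iff intergenic
    distance_to_tss: Optional[int]          # signed, negative = upstream


def _in_any(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _gene_class(pos: int, g: GeneModel) -> Optional[str]:
    """Feature class of ``pos`` with respect to one gene, or None.

    Annotated UTR intervals take precedence over the exon class within the
    gene (UTRs are sub-intervals of exons); across genes the figure-legend
    priority (exon above UTR) applies.
    """
    if _in_any(pos, g.utr5):
        return "utr5"
    if _in_any(pos, g.utr3):
        return "utr3"
    if _in_any(pos, g.exons):
        return "exon"
    if g.body_start <= pos < g.body_end:
        return "intron"
    if g.strand == "+":
        if g.tss - 1000 <= pos < g.tss:
            return "upstream_1k"
        if g.tss - 5000 <= pos < g.tss - 1000:
            return "upstream_5k_1k"
        if g.tts < pos <= g.tts + 1000:
            return "downstream_1k"
    else:
        if g.tss < pos <= g.tss + 1000:
            return "upstream_1k"
        if g.tss + 1000 < pos <= g.tss + 5000:
            return "upstream_5k_1k"
        if g.tts - 1000 <= pos < g.tts:
            return "downstream_1k"
    return None


def strand_distance_to_tss(pos: int, g: GeneModel) -> int:
    """Signed distance to the TSS in transcription orientation
    (negative = upstream of the TSS)."""
    return pos - g.tss if g.strand == "+" else g.tss - pos


class GeneIndex:
    """Per-chromosome gene lookup for classification and target assignment."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chromosome, []).append(g)

    def nearby(self, chromosome: str, pos: int, margin: int = 6000) -> list[GeneModel]:
        out = []
        for g in self.by_chrom.get(chromosome, []):
            if g.body_start - margin <= pos <= g.body_end + margin:
                out.append(g)
        return out


def classify_location(
    snp_id: str, chromosome: str, pos: int, index: GeneIndex
) -> FeatureAssignment:
    """Assign the highest-priority feature class among all nearby genes."""
    best: Optional[tuple[int, int, str, GeneModel]] = None
    for g in index.nearby(chromosome, pos):
        cls = _gene_class(pos, g)
        if cls is None:
            continue
        prio = CLASS_PRIORITY[cls]
        tss_dist = abs(pos - g.tss)
        cand = (prio, -tss_dist, cls, g)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    if best is None:
        return FeatureAssignment(snp_id, "intergenic", None, None)
    _, _, cls, g = best
    return FeatureAssignment(snp_id, cls, g.gene_id, strand_distance_to_tss(pos, g))


def assign_target_genes(
    chromosome: str,
    pos: int,
    index: GeneIndex,
    up: int = 5000,
    down: int = 1000,
    promoter: int = 3000,
) -> list[dict]:
    """Genes for which the position lies within [TSS - up, TTS + down]
    (strand-oriented); every hit gene is reported.

    Each entry carries ``in_promoter``: whether the position lies within
    ``promoter`` bp upstream of the TSS (used for expression linkage).
    """
    out = []
    for g in index.nearby(chromosome, pos, margin=max(up, down) + 1000):
        if g.strand == "+":
            lo, hi = g.tss - up, g.tts + down
        else:
            lo, hi = g.tts - down, g.tss + up
        if lo <= pos <= hi:
            d = strand_distance_to_tss(pos, g)
            out.append({
                "gene_id": g.gene_id,
                "distance_to_tss": d,
                "in_promoter": -promoter <= d < 0,
            })
    out.sort(key=lambda x: (abs(x["distance_to_tss"]), x["gene_id"]))
    return out
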