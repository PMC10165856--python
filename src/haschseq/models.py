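"""Domain types shared by every stage of the HASCh-seq pipeline.

All genomic coordinates are 0-based, half-open intervals.  A run involves
exactly two haplotypes (the two parental genomes of the F1 hybrid), referred
to throughout as ``hap1`` and ``hap2``; their display labels (e.g. "B73",
"Mo17") are carried by :class:`GenomeCoordinate.haplotype_id`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import InputError

CONTEXTS = ("CG", "CHG", "CHH")

#: Genomic feature classes, ordered by annotation priority (highest first).
#: ``utr5``/``utr3`` share one priority tier.
LOCATION_CLASSES = (
    "exon",
    "intron",
    "utr5",
    "utr3",
    "upstream_1k",      # 1 kb upstream .. TSS
    "downstream_1k",    # TTS .. 1 kb downstream
    "upstream_5k_1k",   # 5 kb .. 1 kb upstream
    "intergenic",
)

#: priority rank per class; larger wins.  UTRs tie.
CLASS_PRIORITY = {
    "exon": 6,
    "intron": 5,
    "utr5": 4,
    "utr3": 4,
    "upstream_1k": 3,
    "downstream_1k": 2,
    "upstream_5k_1k": 1,
    "intergenic": 0,
}


@dataclass(frozen=True)
class GenomeCoordinate:
    """A position on one haplotype of the diploid reference."""

    haplotype_id: str
    chromosome: str
    position: int  # 0-based

    def __post_init__(self) -> None:
        if self.position < 0:
            raise InputError(f"negative position {self.position} on {self.chromosome}")


@dataclass
class SnpRecord:
    """A heterozygous SNP with coordinates on both haplotypes and allelic counts.

    ``flank_hap1``/``flank_hap2`` are optional odd-length nucleotide strings
    centred on the SNP base of the respective allele.
    """

    id: str
    coord_hap1: GenomeCoordinate
    coord_hap2: GenomeCoordinate
    allele_hap1: str
    allele_hap2: str
    ip_count_hap1: int
    ip_count_hap2: int
    input_count_hap1: int
    input_count_hap2: int
    flank_hap1: Optional[str] = None
    flank_hap2: Optional[str] = None

    def __post_init__(self) -> None:
        if self.allele_hap1 == self.allele_hap2:
            raise InputError(f"SNP {self.id}: identical alleles {self.allele_hap1}")
        for name in ("ip_count_hap1", "ip_count_hap2", "input_count_hap1", "input_count_hap2"):
            if getattr(self, name) < 0:
                raise InputError(f"SNP {self.id}: negative {name}")
        for fl in (self.flank_hap1, self.flank_hap2):
            if fl is not None and len(fl) % 2 == 0:
                raise InputError(f"SNP {self.id}: flank length {len(fl)} is even")

    @property
    def ip_total(self) -> int:
        return self.ip_count_hap1 + self.ip_count_hap2

    @property
    def f_hap1(self) -> float:
        """IP allele frequency of haplotype 1 (NaN if uncovered)."""
        t = self.ip_total
        return self.ip_count_hap1 / t if t else float("nan")


@dataclass
class Peak:
    """A TF-binding interval on the reference haplotype, with its summit."""

    peak_id: str
    chromosome: str
    start: int
    end: int
    summit: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"peak {self.peak_id}: start {self.start} >= end {self.end}")
        if not self.start <= self.summit < self.end:
            raise InputError(f"peak {self.peak_id}: summit {self.summit} outside [{self.start},{self.end})")

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class GenomicInterval:
    """A generic half-open interval (enhancer, GWAS region, ...)."""

    chromosome: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"interval {self.name}: start {self.start} >= end {self.end}")


@dataclass
class GeneModel:
    """A protein-coding gene model on the reference haplotype.

    ``tss`` and ``tts`` are the genomic positions (0-based) of transcription
    start and termination; for a minus-strand gene ``tss > tts``.  Exon and
    UTR intervals are half-open in genomic coordinates, sorted ascending.
    """

    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    tss: int
    tts: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.strand == "+" and self.tss > self.tts:
            raise InputError(f"gene {self.gene_id}: tss > tts on + strand")
        if self.strand == "-" and self.tss < self.tts:
            raise InputError(f"gene {self.gene_id}: tss < tts on - strand")
        prev_end = None
        for s, e in self.exons:
            if prev_end is not None and s < prev_end:
                raise InputError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def body_end(self) -> int:
        """Half-open end of the transcribed interval."""
        return max(self.tss, self.tts) + 1


class MethylationTrack:
    """Per-cytosine methylation counts for one haplotype and one context.

    Wraps a DataFrame with columns ``chromosome, position, methylated,
    total`` sorted by (chromosome, position); rows with ``total == 0`` are
    retained but carry no evidence (flagged via :attr:`n_uncovered`).
    """

    def __init__(self, haplotype_id: str, context: str, records: pd.DataFrame):
        if context not in CONTEXTS:
            raise InputError(f"unknown methylation context {context!r}")
        required = {"chromosome", "position", "methylated", "total"}
        missing = required - set(records.columns)
        if missing:
            raise InputError(f"methylation table missing columns: {sorted(missing)}")
        if (records["methylated"] > records["total"]).any():
            raise InputError("methylated reads exceed total reads")
        df = records.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(["chromosome", "position"])
        # duplicate positions are pooled (split records carry the same evidence)
        if dup.any():
            df = df.groupby(["chromosome", "position"], as_index=False)[["methylated", "total"]].sum()
            df = df.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
        self.haplotype_id = haplotype_id
        self.context = context
        self.df = df
        self.n_uncovered = int((df["total"] == 0).sum())
        self._by_chrom = {c: g.reset_index(drop=True) for c, g in df.groupby("chromosome")}

    def window_counts(self, chromosome: str, start: int, end: int) -> tuple[int, int]:
        """Pooled (methylated, total) reads over cytosines in [start, end)."""
        g = self._by_chrom.get(chromosome)
        if g is None:
            return 0, 0
        pos = g["position"].to_numpy()
        lo = pos.searchsorted(start, side="left")
        hi = pos.searchsorted(end, side="left")
        if hi <= lo:
            return 0, 0
        return int(g["methylated"].to_numpy()[lo:hi].sum()), int(g["total"].to_numpy()[lo:hi].sum())

    def window_fractions(self, chromosome: str, start: int, end: int) -> pd.DataFrame:
        """Per-cytosine rows in [start, end) with a ``fraction`` column (covered only)."""
        g = self._by_chrom.get(chromosome)
        if g is None:
            return pd.DataFrame(columns=["position", "methylated", "total", "fraction"])
        pos = g["position"].to_numpy()
        lo = pos.searchsorted(start, side="left")
        hi = pos.searchsorted(end, side="left")
        sub = g.iloc[lo:hi]
        sub = sub[sub["total"] > 0].copy()
        sub["fraction"] = sub["methylated"] / sub["total"]
        return sub[["position", "methylated", "total", "fraction"]]

    def __len__(self) -> int:
        return len(self.df)
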