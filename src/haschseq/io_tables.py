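"""Readers and writers for every external table the pipeline touches.

All tabular files are tab-separated text whose header is the first line,
prefixed with ``#``.  Interval files are BED dialect (0-based half-open);
GFF3 is 1-based closed and converted to the internal 0-based half-open
convention at parse time, never afterwards.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConfigError, InputError
from .models import (
    CONTEXTS,
    GeneModel,
    GenomeCoordinate,
    GenomicInterval,
    MethylationTrack,
    Peak,
    SnpRecord,
)

SNP_COLUMNS = [
    "id",
    "chrom_hap1", "pos_hap1", "allele_hap1",
    "chrom_hap2", "pos_hap2", "allele_hap2",
    "ip_count_hap1", "ip_count_hap2",
    "input_count_hap1", "input_count_hap2",
    "flank_hap1", "flank_hap2",
]

MISSING = "."


def _read_commented_tsv(path: str) -> pd.DataFrame:
    """Read a TSV whose header line starts with '#'."""
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise InputError(f"{path}: empty file")
        names = header.lstrip("#").strip().split("\t")
        body = fh.read()
    if not body.strip():
        return pd.DataFrame(columns=names)
    df = pd.read_csv(io.StringIO(body), sep="\t", names=names, dtype=str, comment="#")
    return df


def _write_commented_tsv(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def _parse_int(value: str, path: str, row: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise InputError(f"{path}: row {row}: column {column!r} is not an integer: {value!r}")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(
    path: str,
    format_spec: Optional[dict[str, str]] = None,
    hap1: str = "hap1",
    hap2: str = "hap2",
) -> list[SnpRecord]:
    """Read a per-SNP allelic count table.

    ``format_spec`` maps canonical column names (see :data:`SNP_COLUMNS`)
    to the column names actually present in the file; identity by default.
    Flank columns are optional; ``.`` denotes a missing flank.
    """
    df = _read_commented_tsv(path)
    spec = dict(format_spec or {})
    colmap = {canon: spec.get(canon, canon) for canon in SNP_COLUMNS}
    mandatory = [c for c in SNP_COLUMNS if not c.startswith("flank")]
    for canon in mandatory:
        if colmap[canon] not in df.columns:
            raise ConfigError(f"{path}: missing mandatory column {colmap[canon]!r} (for {canon!r})")

    records: list[SnpRecord] = []
    seen: set[str] = set()
    has_flanks = colmap["flank_hap1"] in df.columns and colmap["flank_hap2"] in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row_d = dict(zip(df.columns, row))
        sid = row_d[colmap["id"]]
        if sid in seen:
            raise InputError(f"{path}: row {i}: duplicate SNP id {sid!r}")
        seen.add(sid)
        try:
            rec = SnpRecord(
                id=sid,
                coord_hap1=GenomeCoordinate(
                    hap1, row_d[colmap["chrom_hap1"]],
                    _parse_int(row_d[colmap["pos_hap1"]], path, i, "pos_hap1")),
                coord_hap2=GenomeCoordinate(
                    hap2, row_d[colmap["chrom_hap2"]],
                    _parse_int(row_d[colmap["pos_hap2"]], path, i, "pos_hap2")),
                allele_hap1=row_d[colmap["allele_hap1"]],
                allele_hap2=row_d[colmap["allele_hap2"]],
                ip_count_hap1=_parse_int(row_d[colmap["ip_count_hap1"]], path, i, "ip_count_hap1"),
                ip_count_hap2=_parse_int(row_d[colmap["ip_count_hap2"]], path, i, "ip_count_hap2"),
                input_count_hap1=_parse_int(row_d[colmap["input_count_hap1"]], path, i, "input_count_hap1"),
                input_count_hap2=_parse_int(row_d[colmap["input_count_hap2"]], path, i, "input_count_hap2"),
                flank_hap1=(None if not has_flanks or row_d[colmap["flank_hap1"]] in (MISSING, None, "")
                            else row_d[colmap["flank_hap1"]]),
                flank_hap2=(None if not has_flanks or row_d[colmap["flank_hap2"]] in (MISSING, None, "")
                            else row_d[colmap["flank_hap2"]]),
            )
        except InputError as exc:
            raise InputError(f"{path}: row {i}: {exc}") from None
        records.append(rec)
    return records


def write_snp_table(records: Iterable[SnpRecord], path: str) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "chrom_hap1": r.coord_hap1.chromosome, "pos_hap1": r.coord_hap1.position,
            "allele_hap1": r.allele_hap1,
            "chrom_hap2": r.coord_hap2.chromosome, "pos_hap2": r.coord_hap2.position,
            "allele_hap2": r.allele_hap2,
            "ip_count_hap1": r.ip_count_hap1, "ip_count_hap2": r.ip_count_hap2,
            "input_count_hap1": r.input_count_hap1, "input_count_hap2": r.input_count_hap2,
            "flank_hap1": r.flank_hap1 or MISSING, "flank_hap2": r.flank_hap2 or MISSING,
        })
    _write_commented_tsv(pd.DataFrame(rows, columns=SNP_COLUMNS), path)


# ---------------------------------------------------------------------------
# BED-like intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str, kind: str = "generic"):
    """Read a BED file as peaks or generic intervals.

    ``kind='peak'`` expects an absolute summit coordinate in column 7; if
    absent, the interval midpoint is used and a warning is emitted.
    Other kinds (``gwas_hit``, ``enhancer``, ``generic``) return
    :class:`GenomicInterval` objects, sorted per chromosome.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            if start >= end:
                raise InputError(f"{path}: line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] else MISSING
            if kind == "peak":
                score = None
                if len(fields) > 4 and fields[4] not in (MISSING, ""):
                    score = float(fields[4])
                if len(fields) > 6 and fields[6] not in (MISSING, ""):
                    summit = _parse_int(fields[6], path, lineno, "summit")
                else:
                    summit = (start + end) // 2
                    warnings.warn(f"{path}: line {lineno}: peak without summit, using midpoint")
                pid = name if name != MISSING else f"peak_{lineno}"
                out.append(Peak(peak_id=pid, chromosome=chrom, start=start, end=end,
                                summit=summit, score=score))
            else:
                out.append(GenomicInterval(chromosome=chrom, start=start, end=end, name=name))
    out.sort(key=lambda iv: (iv.chromosome, iv.start, iv.end))
    return out


def write_intervals(intervals, path: str) -> None:
    """Write peaks or generic intervals as BED (peaks carry summit in col 7)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, Peak):
                score = MISSING if iv.score is None else f"{iv.score:g}"
                fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.peak_id}\t{score}\t.\t{iv.summit}\n")
            else:
                fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str) -> list[GeneModel]:
    """Parse gene/mRNA/exon/UTR features from a GFF3 file.

    1-based closed GFF coordinates are converted to 0-based half-open.
    Exons and UTRs of all mRNA isoforms of a gene are merged into one
    per-gene model (union of intervals).
    """
    import gffutils

    try:
        db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:  # gffutils raises plain ValueError on bad files
        raise InputError(f"{path}: failed to parse GFF3: {exc}") from None

    # children must name a parent; enforce the contract explicitly
    for feat in db.all_features():
        if feat.featuretype in ("exon", "five_prime_UTR", "three_prime_UTR", "CDS", "mRNA"):
            if "Parent" not in feat.attributes:
                raise InputError(
                    f"{path}: {feat.featuretype} at {feat.seqid}:{feat.start} missing Parent attribute")

    def _merged(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
        if not intervals:
            return []
        intervals = sorted(intervals)
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [tuple(x) for x in merged]

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons, utr5, utr3 = [], [], []
        for ftype, bucket in (("exon", exons), ("five_prime_UTR", utr5),
                              ("three_prime_UTR", utr3)):
            for feat in db.children(gene, featuretype=ftype):
                bucket.append((feat.start - 1, feat.end))  # to 0-based half-open
        start0, end0 = gene.start - 1, gene.end  # half-open
        strand = gene.strand if gene.strand in "+-" else "+"
        tss = start0 if strand == "+" else end0 - 1
        tts = end0 - 1 if strand == "+" else start0
        genes.append(GeneModel(
            gene_id=gene.id, chromosome=gene.seqid, strand=strand,
            tss=tss, tts=tts,
            exons=_merged(exons), utr5=_merged(utr5), utr3=_merged(utr3)))
    genes.sort(key=lambda g: (g.chromosome, g.body_start))
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon/UTR lines)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.body_start + 1, g.body_end - 1 + 1  # to 1-based closed
            fh.write(f"{g.chromosome}\t.\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{g.chromosome}\t.\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            for ftype, ivs in (("exon", g.exons), ("five_prime_UTR", g.utr5),
                               ("three_prime_UTR", g.utr3)):
                for s, e in ivs:
                    fh.write(f"{g.chromosome}\t.\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mid}\n")


# ---------------------------------------------------------------------------
# Methylation tables
# ---------------------------------------------------------------------------

def read_methylation(path: str, haplotype_id: str, context: str) -> MethylationTrack:
    """Read a per-cytosine table (chromosome, position, methylated, total)."""
    if context not in CONTEXTS:
        raise ConfigError(f"unknown methylation context {context!r}; expected one of {CONTEXTS}")
    df = _read_commented_tsv(path)
    required = ["chromosome", "position", "methylated", "total"]
    for col in required:
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column {col!r}")
    try:
        df = df.astype({"position": int, "methylated": int, "total": int})
    except ValueError as exc:
        raise InputError(f"{path}: non-integer value in methylation table: {exc}") from None
    return MethylationTrack(haplotype_id, context, df[required])


def write_methylation(track: MethylationTrack, path: str) -> None:
    _write_commented_tsv(track.df[["chromosome", "position", "methylated", "total"]], path)


# ---------------------------------------------------------------------------
# Allele-resolved expression tables
# ---------------------------------------------------------------------------

def read_expression(path: str) -> pd.DataFrame:
    """Read an allele-resolved expression count table.

    Requires ``gene_id`` plus either pooled columns ``reads_hap1``/
    ``reads_hap2`` or per-replicate pairs ``reads_hap1_r<i>``/``reads_hap2_r<i>``.
    """
    df = _read_commented_tsv(path)
    if "gene_id" not in df.columns:
        raise ConfigError(f"{path}: missing column 'gene_id'")
    count_cols = [c for c in df.columns if c.startswith(("reads_hap1", "reads_hap2"))]
    if not count_cols:
        raise ConfigError(f"{path}: no read-count columns found")
    try:
        df[count_cols] = df[count_cols].astype(int)
    except ValueError as exc:
        raise InputError(f"{path}: non-integer read count: {exc}") from None
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise InputError(f"{path}: duplicate gene_id {dup!r}")
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write any result DataFrame as commented-header TSV."""
    _write_commented_tsv(df, path)


def read_table(path: str) -> pd.DataFrame:
    """Read back a commented-header TSV written by :func:`write_table`."""
    df = _read_commented_tsv(path)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if len(df) and converted.notna().all():
            df[col] = converted
    return df
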