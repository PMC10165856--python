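"""Synthetic HASCh-seq data with known ground truth.

Generates a complete, self-consistent input bundle — allelic SNP counts,
binding peaks with summits, allelic flank sequences, per-context
methylation tracks for both haplotypes, gene models, GWAS hits, enhancer
intervals, allele-resolved expression counts — plus a truth table
recording every planted property, so each pipeline stage can be tested
without external downloads.

The generative model: null SNPs draw IP counts Binomial(depth,
global_bias); true ASBs draw Beta-Binomial with a planted bias
(overdispersion rho represents replicate-level extra variance);
motif-driven ASBs carry a canonical BRRE/G-box on the high-binding allele
that the SNP destroys on the other; methylation-driven ASBs carry a
>=70%/<=10% CG differential in the +/-20 bp window with the
hypermethylated allele on the low-binding side; input counts are null
everywhere except planted mapping-artifact loci, which are biased in both
IP and input.  All randomness flows from one seed through a named
generator hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .models import (
    GeneModel,
    GenomeCoordinate,
    GenomicInterval,
    MethylationTrack,
    Peak,
    SnpRecord,
)
from .motifs import BZR1_MOTIFS, IUPAC, MotifSet, _covers_center

BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Defaults define the standard study conditions of the generator."""

    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_peaks: int = 120
    peak_width_min: int = 200
    peak_width_max: int = 600
    n_true_asbs: int = 50
    n_null_snps: int = 500
    asb_bias: float = 0.9                   # per-ASB allele-frequency bias
    overdispersion_rho: float = 0.01        # beta-binomial rho
    global_bias: float = 0.494              # null hap1 allele frequency
    fraction_motif_driven: float = 0.4
    fraction_methylation_driven: float = 0.3
    ip_depth_mean: float = 60.0
    input_depth_mean: float = 60.0
    depth_jitter: bool = False              # False: fixed depth; True: Poisson
    fraction_input_artifacts: float = 0.02  # of null SNPs; biased in IP and input
    input_artifact_bias: float = 0.95
    flank_halfwidth: int = 100
    fraction_null_in_peaks: float = 0.7
    gene_probability: float = 0.7           # P(a true ASB gets a promoter gene)
    n_background_genes: int = 60
    gene_length: int = 2000
    utr_length: int = 150
    fraction_gwas_linked: float = 0.3
    n_gwas_background: int = 80
    gwas_traits: tuple = ("growth", "height", "flowering", "disease", "yield")
    gwas_linked_trait: str = "growth"
    n_enhancers: int = 30
    enhancer_width: int = 1000
    fraction_enhancer_linked: float = 0.3
    expression_depth: float = 200.0
    fraction_expression_coupled: float = 0.6
    methylation_read_depth: float = 20.0
    methylation_span: int = 2000
    methylation_spacing: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_motif_driven + self.fraction_methylation_driven <= 1:
            raise ConfigError("cause fractions must lie in [0,1] and sum to <= 1")
        per_chrom = self.n_peaks // self.n_chromosomes
        if per_chrom * (self.peak_width_max + 200) > self.chromosome_length:
            raise ConfigError("chromosome_length cannot accommodate the requested peaks")
        if self.n_true_asbs > self.n_peaks:
            raise ConfigError("need at least one peak per true ASB")


@dataclass
class SimulatedBundle:
    snps: list
    peaks: list
    genes: list
    methylation: dict                       # (haplotype, context) -> MethylationTrack
    gwas: pd.DataFrame                      # chromosome, position, trait
    enhancers: list
    expression: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _beta_binomial(rng: np.random.Generator, n: int, mean: float, rho: float) -> int:
    if rho <= 0:
        return int(rng.binomial(n, mean))
    s = 1.0 / rho - 1.0
    p = rng.beta(mean * s, (1.0 - mean) * s)
    return int(rng.binomial(n, p))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _resolve_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(IUPAC[b][rng.integers(0, len(IUPAC[b]))] for b in pattern)


_CANONICAL = BZR1_MOTIFS


def _center_is_clean(seq: str) -> bool:
    c = len(seq) // 2
    return not any(_covers_center(seq, ms.patterns, c) for ms in _CANONICAL)


def _make_flanks(
    rng: np.random.Generator,
    halfwidth: int,
    motif_driven: bool,
    motif_set: Optional[MotifSet] = None,
) -> tuple[str, str, str, str, Optional[str]]:
    """Build (flank_high, flank_low, allele_high, allele_low, motif_name).

    Flanks are identical except the central base.  For motif-driven loci a
    canonical motif instance overlapping the centre is planted on the
    high-affinity allele and destroyed by the centre substitution on the
    low-affinity allele; for all other loci neither allele carries a
    canonical motif overlapping the centre.
    """
    width = 2 * halfwidth + 1
    center = halfwidth
    for _ in range(200):
        seq = list(_random_seq(rng, width))
        if motif_driven:
            ms = motif_set or _CANONICAL[int(rng.integers(0, len(_CANONICAL)))]
            pattern = ms.patterns[int(rng.integers(0, len(ms.patterns)))]
            L = len(pattern)
            start = center - int(rng.integers(0, L))  # match covers the centre
            if start < 0 or start + L > width:
                continue
            concrete = _resolve_iupac(rng, pattern)
            seq[start:start + L] = concrete
            high = "".join(seq)
            if not _covers_center(high, ms.patterns, center):
                continue
            allele_high = high[center]
            # substitute the centre so every canonical match there dies
            candidates = [b for b in BASES if b != allele_high]
            rng.shuffle(candidates)
            for b in candidates:
                low = high[:center] + b + high[center + 1:]
                if _center_is_clean(low):
                    return high, low, allele_high, b, ms.name
            continue
        high = "".join(seq)
        if not _center_is_clean(high):
            continue
        allele_high = high[center]
        candidates = [b for b in BASES if b != allele_high]
        rng.shuffle(candidates)
        for b in candidates:
            low = high[:center] + b + high[center + 1:]
            if _center_is_clean(low):
                return high, low, allele_high, b, None
    raise RuntimeError("failed to generate flank sequences (should not happen)")


def simulate_dataset(config: Optional[SimulationConfig] = None, seed: Optional[int] = None) -> SimulatedBundle:
    """Generate the full synthetic input bundle; byte-stable given the seed."""
    cfg = config or SimulationConfig()
    root_seed = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence(root_seed).spawn(8)
    rng_peaks, rng_snps, rng_counts, rng_flanks, rng_meth, rng_gwas, rng_genes, rng_expr = (
        np.random.default_rng(s) for s in streams)

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # ---- peaks: non-overlapping, one per evenly spaced slot ----------------
    peaks: list[Peak] = []
    per_chrom = cfg.n_peaks // cfg.n_chromosomes
    extras = cfg.n_peaks - per_chrom * cfg.n_chromosomes
    pk = 0
    for ci, chrom in enumerate(chroms):
        n_here = per_chrom + (1 if ci < extras else 0)
        slot = cfg.chromosome_length // max(n_here, 1)
        for j in range(n_here):
            width = int(rng_peaks.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
            lo = j * slot + 100
            hi = (j + 1) * slot - width - 100
            start = int(rng_peaks.integers(lo, max(lo + 1, hi)))
            end = start + width
            summit = int(rng_peaks.integers(start + width // 4, end - width // 4))
            peaks.append(Peak(f"peak_{pk}", chrom, start, end, summit))
            pk += 1

    # ---- SNP placement -----------------------------------------------------
    n_motif = int(round(cfg.fraction_motif_driven * cfg.n_true_asbs))
    n_meth = int(round(cfg.fraction_methylation_driven * cfg.n_true_asbs))
    causes = (["motif"] * n_motif + ["methylation"] * n_meth
              + ["other"] * (cfg.n_true_asbs - n_motif - n_meth))
    rng_snps.shuffle(causes)

    asb_peaks = list(rng_snps.choice(len(peaks), size=cfg.n_true_asbs, replace=False))
    used_positions: dict[str, set[int]] = {c: set() for c in chroms}
    truth_rows: list[dict] = []
    snps: list[SnpRecord] = []

    def _unique_pos(chrom: str, pos: int) -> int:
        while pos in used_positions[chrom]:
            pos += 1
        used_positions[chrom].add(pos)
        return pos

    n_artifacts = int(round(cfg.fraction_input_artifacts * cfg.n_null_snps))
    n_in_peak_null = int(round(cfg.fraction_null_in_peaks * (cfg.n_null_snps - n_artifacts)))

    def _depth(mean: float, at_least_one: bool = False) -> int:
        n = int(rng_counts.poisson(mean)) if cfg.depth_jitter else int(round(mean))
        return max(1, n) if at_least_one else n

    def _counts(kind: str, direction_hap1: bool) -> tuple[int, int, int, int, float]:
        n_ip = _depth(cfg.ip_depth_mean, at_least_one=True)
        n_in = _depth(cfg.input_depth_mean)
        if kind == "true":
            bias = cfg.asb_bias if direction_hap1 else 1.0 - cfg.asb_bias
            k_ip = _beta_binomial(rng_counts, n_ip, bias, cfg.overdispersion_rho)
            k_in = int(rng_counts.binomial(n_in, cfg.global_bias)) if n_in else 0
        elif kind == "artifact":
            bias = cfg.input_artifact_bias if direction_hap1 else 1.0 - cfg.input_artifact_bias
            k_ip = int(rng_counts.binomial(n_ip, bias))
            k_in = int(rng_counts.binomial(n_in, bias)) if n_in else 0
        else:
            bias = cfg.global_bias
            k_ip = int(rng_counts.binomial(n_ip, cfg.global_bias))
            k_in = int(rng_counts.binomial(n_in, cfg.global_bias)) if n_in else 0
        return k_ip, n_ip - k_ip, k_in, n_in - k_in, bias

    def _add_snp(sid: str, chrom: str, pos: int, kind: str, cause: str,
                 peak_id: str, motif_driven: bool,
                 direction: Optional[bool] = None) -> dict:
        direction_hap1 = bool(rng_counts.random() < 0.5) if direction is None else direction
        ip1, ip2, in1, in2, bias = _counts(kind, direction_hap1)
        fh, fl, ah, al, motif_name = _make_flanks(
            rng_flanks, cfg.flank_halfwidth, motif_driven and direction_is_relevant(kind))
        # hap1 carries the high-affinity sequence iff the bias points to hap1
        if direction_hap1:
            flank1, flank2, a1, a2 = fh, fl, ah, al
        else:
            flank1, flank2, a1, a2 = fl, fh, al, ah
        snps.append(SnpRecord(
            id=sid,
            coord_hap1=GenomeCoordinate("hap1", chrom, pos),
            coord_hap2=GenomeCoordinate("hap2", chrom, pos),
            allele_hap1=a1, allele_hap2=a2,
            ip_count_hap1=ip1, ip_count_hap2=ip2,
            input_count_hap1=in1, input_count_hap2=in2,
            flank_hap1=flank1, flank_hap2=flank2))
        row = {
            "snp_id": sid, "chromosome": chrom, "position": pos, "peak_id": peak_id,
            "is_asb": kind == "true", "cause": cause,
            "planted_bias_hap1": bias,
            "direction": "hap1" if direction_hap1 else "hap2",
            "motif_name": motif_name or ".",
            "input_artifact": kind == "artifact",
            "gwas_linked": False, "enhancer_linked": False,
            "gene_id": ".", "expression_coupled": False,
        }
        truth_rows.append(row)
        return row

    def direction_is_relevant(kind: str) -> bool:
        return kind == "true"

    # true ASBs, one per chosen peak, close to the summit
    for i, (pi, cause) in enumerate(zip(asb_peaks, causes)):
        p = peaks[pi]
        pos = int(np.clip(p.summit + rng_snps.integers(-10, 11), p.start, p.end - 1))
        pos = _unique_pos(p.chromosome, pos)
        _add_snp(f"asb_{i}", p.chromosome, pos, "true", cause, p.peak_id,
                 motif_driven=(cause == "motif"))

    # planted input artifacts inside peaks not already hosting a true ASB
    # (artifact loci arise from independent mapping problems)
    free_peaks = [i for i in range(len(peaks)) if i not in set(asb_peaks)]
    artifact_peaks = (rng_snps.choice(free_peaks, size=n_artifacts,
                                      replace=len(free_peaks) < n_artifacts)
                      if n_artifacts and free_peaks else [])
    artifact_direction: dict[int, bool] = {}
    for i, pi in enumerate(artifact_peaks):
        p = peaks[int(pi)]
        direction = artifact_direction.setdefault(int(pi), bool(rng_counts.random() < 0.5))
        pos = _unique_pos(p.chromosome, int(rng_snps.integers(p.start, p.end)))
        _add_snp(f"artifact_{i}", p.chromosome, pos, "artifact", "artifact", p.peak_id,
                 False, direction=direction)

    # null SNPs: most inside peaks, the rest intergenic.  A null SNP landing
    # in an artifact peak shares the regional mapping bias (mapping problems
    # affect the whole misaligned segment, not single positions).
    artifact_peak_set = {int(i) for i in artifact_peaks}
    peak_spans = {c: [(p.start, p.end) for p in peaks if p.chromosome == c] for c in chroms}
    n_null = cfg.n_null_snps - n_artifacts
    for i in range(n_null):
        if i < n_in_peak_null:
            pi = int(rng_snps.integers(0, len(peaks)))
            p = peaks[pi]
            pos = _unique_pos(p.chromosome, int(rng_snps.integers(p.start, p.end)))
            if pi in artifact_peak_set:
                _add_snp(f"null_{i}", p.chromosome, pos, "artifact", "artifact", p.peak_id,
                         False, direction=artifact_direction[pi])
            else:
                _add_snp(f"null_{i}", p.chromosome, pos, "null", "null", p.peak_id, False)
        else:
            chrom = chroms[int(rng_snps.integers(0, len(chroms)))]
            for _ in range(100):
                pos = int(rng_snps.integers(0, cfg.chromosome_length))
                if not any(s <= pos < e for s, e in peak_spans[chrom]):
                    break
            pos = _unique_pos(chrom, pos)
            _add_snp(f"null_{i}", chrom, pos, "null", "null", ".", False)

    truth = pd.DataFrame(truth_rows)
    truth_idx = {r["snp_id"]: i for i, r in enumerate(truth_rows)}

    # ---- gene models -------------------------------------------------------
    genes: list[GeneModel] = []

    def _make_gene(gid: str, chrom: str, tss: int, strand: str) -> Optional[GeneModel]:
        L, U = cfg.gene_length, cfg.utr_length
        if strand == "+":
            start, end = tss, tss + L          # body half-open [start, end)
            tts = end - 1
        else:
            start, end = tss - L + 1, tss + 1
            tts = start
        if start < 0 or end > cfg.chromosome_length:
            return None
        # two exons separated by one intron; UTRs at the transcript ends
        intron_lo = start + L // 3
        intron_hi = start + 2 * L // 3
        exons = [(start, intron_lo), (intron_hi, end)]
        if strand == "+":
            utr5, utr3 = [(start, start + U)], [(end - U, end)]
        else:
            utr5, utr3 = [(end - U, end)], [(start, start + U)]
        return GeneModel(gene_id=gid, chromosome=chrom, strand=strand, tss=tss,
                         tts=tts, exons=exons, utr5=utr5, utr3=utr3)

    asb_rows = [r for r in truth_rows if r["is_asb"]]
    n_coupled_target = int(round(cfg.fraction_expression_coupled * len(asb_rows)))
    n_with_gene = 0
    for i, row in enumerate(asb_rows):
        if rng_genes.random() >= cfg.gene_probability:
            continue
        strand = "+" if rng_genes.random() < 0.5 else "-"
        offset = int(rng_genes.integers(200, 2500))
        tss = row["position"] + offset if strand == "+" else row["position"] - offset
        g = _make_gene(f"gene_asb_{i}", row["chromosome"], tss, strand)
        if g is None:
            continue
        genes.append(g)
        truth.loc[truth_idx[row["snp_id"]], "gene_id"] = g.gene_id
        row["gene_id"] = g.gene_id
        n_with_gene += 1
    for i in range(cfg.n_background_genes):
        chrom = chroms[int(rng_genes.integers(0, len(chroms)))]
        tss = int(rng_genes.integers(10_000, cfg.chromosome_length - 10_000))
        strand = "+" if rng_genes.random() < 0.5 else "-"
        g = _make_gene(f"gene_bg_{i}", chrom, tss, strand)
        if g is not None:
            genes.append(g)
    genes.sort(key=lambda g: (g.chromosome, g.body_start))

    # ---- methylation tracks ------------------------------------------------
    meth_rows: dict[tuple[str, str], list] = {
        (h, c): [] for h in ("hap1", "hap2") for c in ("CG", "CHG", "CHH")}

    def _meth_level(cause_row: dict, hap: str, offset: int, context: str) -> float:
        if cause_row["cause"] == "methylation" and context == "CG":
            low_hap = "hap2" if cause_row["direction"] == "hap1" else "hap1"
            if hap == low_hap:  # hypermethylated, low-affinity allele
                if abs(offset) <= 20:
                    return 0.85
                if abs(offset) <= 100:
                    return 0.30
        return 0.03

    for row in truth_rows:
        if not row["is_asb"]:
            continue
        chrom, pos = row["chromosome"], row["position"]
        offsets = np.arange(-cfg.methylation_span, cfg.methylation_span + 1,
                            cfg.methylation_spacing)
        for context in ("CG", "CHG", "CHH"):
            for hap in ("hap1", "hap2"):
                levels = np.array([_meth_level(row, hap, int(o), context) for o in offsets])
                totals = rng_meth.poisson(cfg.methylation_read_depth, size=len(offsets))
                meths = rng_meth.binomial(totals, levels)
                bucket = meth_rows[(hap, context)]
                for o, m, t in zip(offsets, meths, totals):
                    bucket.append((chrom, pos + int(o), int(m), int(t)))

    methylation = {}
    for key, rows in meth_rows.items():
        df = pd.DataFrame(rows, columns=["chromosome", "position", "methylated", "total"])
        methylation[key] = MethylationTrack(key[0], key[1], df)

    # ---- GWAS hits ---------------------------------------------------------
    n_linked = int(round(cfg.fraction_gwas_linked * len(asb_rows)))
    linked_idx = rng_gwas.choice(len(asb_rows), size=n_linked, replace=False) if n_linked else []
    gwas_rows = []
    for i in linked_idx:
        row = asb_rows[i]
        gwas_rows.append({
            "chromosome": row["chromosome"],
            "position": max(0, row["position"] + int(rng_gwas.integers(-1900, 1901))),
            "trait": cfg.gwas_linked_trait,
        })
        truth.loc[truth_idx[row["snp_id"]], "gwas_linked"] = True
    for _ in range(cfg.n_gwas_background):
        gwas_rows.append({
            "chromosome": chroms[int(rng_gwas.integers(0, len(chroms)))],
            "position": int(rng_gwas.integers(0, cfg.chromosome_length)),
            "trait": cfg.gwas_traits[int(rng_gwas.integers(0, len(cfg.gwas_traits)))],
        })
    gwas = pd.DataFrame(gwas_rows)

    # ---- enhancers ---------------------------------------------------------
    n_enh_linked = min(int(round(cfg.fraction_enhancer_linked * len(asb_rows))), len(asb_rows))
    enh_idx = rng_gwas.choice(len(asb_rows), size=n_enh_linked, replace=False) if n_enh_linked else []
    enhancers: list[GenomicInterval] = []
    for j, i in enumerate(enh_idx):
        row = asb_rows[i]
        center = row["position"] + int(rng_gwas.integers(-200, 201))
        start = max(0, center - cfg.enhancer_width // 2)
        enhancers.append(GenomicInterval(row["chromosome"], start,
                                         start + cfg.enhancer_width, f"enh_linked_{j}"))
        truth.loc[truth_idx[row["snp_id"]], "enhancer_linked"] = True
    for j in range(cfg.n_enhancers - n_enh_linked):
        chrom = chroms[int(rng_gwas.integers(0, len(chroms)))]
        start = int(rng_gwas.integers(0, cfg.chromosome_length - cfg.enhancer_width))
        enhancers.append(GenomicInterval(chrom, start, start + cfg.enhancer_width,
                                         f"enh_bg_{j}"))
    enhancers.sort(key=lambda e: (e.chromosome, e.start))

    # ---- expression --------------------------------------------------------
    expr_rows = []
    asb_gene_rows = [r for r in asb_rows if r["gene_id"] != "."]
    coupled_flags = np.zeros(len(asb_gene_rows), dtype=bool)
    n_coupled = min(n_coupled_target, len(asb_gene_rows))
    if n_coupled:
        coupled_flags[rng_expr.choice(len(asb_gene_rows), size=n_coupled, replace=False)] = True
    for row, coupled in zip(asb_gene_rows, coupled_flags):
        depth = max(MIN_EXPR_DEPTH, int(rng_expr.poisson(cfg.expression_depth)))
        if coupled:
            # the TF activates some targets and represses others, so the
            # expression bias follows the binding bias for only half of them
            repressing = bool(rng_expr.random() < 0.5)
            toward_hap1 = (row["direction"] == "hap1") != repressing
            f = 0.75 if toward_hap1 else 0.25
            truth.loc[truth_idx[row["snp_id"]], "expression_coupled"] = True
        else:
            f = 0.5
        k = int(rng_expr.binomial(depth, f))
        expr_rows.append({"gene_id": row["gene_id"], "reads_hap1": k, "reads_hap2": depth - k})
    for g in genes:
        if g.gene_id.startswith("gene_bg_"):
            depth = max(MIN_EXPR_DEPTH, int(rng_expr.poisson(cfg.expression_depth)))
            k = int(rng_expr.binomial(depth, 0.5))
            expr_rows.append({"gene_id": g.gene_id, "reads_hap1": k, "reads_hap2": depth - k})
    expression = pd.DataFrame(expr_rows)

    return SimulatedBundle(snps=snps, peaks=peaks, genes=genes, methylation=methylation,
                           gwas=gwas, enhancers=enhancers, expression=expression,
                           truth=truth, config=cfg)


MIN_EXPR_DEPTH = 25


# ---------------------------------------------------------------------------
# bundle serialisation (the same formats io_tables reads)
# ---------------------------------------------------------------------------

def write_bundle(bundle: SimulatedBundle, out_dir: str) -> dict[str, str]:
    """Write every bundle component to ``out_dir``; returns name -> path."""
    import os

    from . import io_tables

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    paths["snps"] = os.path.join(out_dir, "snps.tsv")
    io_tables.write_snp_table(bundle.snps, paths["snps"])

    paths["peaks"] = os.path.join(out_dir, "peaks.bed")
    io_tables.write_intervals(bundle.peaks, paths["peaks"])

    paths["genes"] = os.path.join(out_dir, "genes.gff3")
    io_tables.write_gff3_genes(bundle.genes, paths["genes"])

    for (hap, ctx), track in bundle.methylation.items():
        key = f"meth_{hap}_{ctx}"
        paths[key] = os.path.join(out_dir, f"{key}.tsv")
        io_tables.write_methylation(track, paths[key])

    paths["gwas"] = os.path.join(out_dir, "gwas.tsv")
    io_tables.write_table(bundle.gwas, paths["gwas"])

    paths["enhancers"] = os.path.join(out_dir, "enhancers.bed")
    io_tables.write_intervals(bundle.enhancers, paths["enhancers"])

    paths["expression"] = os.path.join(out_dir, "expression.tsv")
    io_tables.write_table(bundle.expression, paths["expression"])

    paths["truth"] = os.path.join(out_dir, "truth.tsv")
    io_tables.write_table(bundle.truth, paths["truth"])
    return paths
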