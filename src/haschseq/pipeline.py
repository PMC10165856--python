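"""End-to-end orchestration of the analysis stages on one input bundle.

``run_pipeline`` chains ASB calling, feature annotation, background
sampling, motif-variant classification, haplotype-methylation
classification, enrichment against GWAS/enhancer sets, and ASE linkage,
and collects per-stage counts in a run report.  It operates on an
in-memory :class:`~haschseq.simulate.SimulatedBundle`-shaped object; the
CLI assembles the same shape from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import annotation, ase, background, enrichment, methylation, motifs
from .asb import AsbConfig, AsbResult, call_asbs, coverage_filter


@dataclass
class PipelineResult:
    asb: AsbResult
    annotations: list                           # FeatureAssignment per lead call
    background: Optional[background.BackgroundSample]
    motif_calls: list
    motif_summary: dict                         # per motif-set canonical bias
    methylation_calls: dict                     # context -> list[AsbMethylation]
    enhancer_enrichment: Optional[enrichment.EnrichmentResult]
    gwas_enrichment: Optional[pd.DataFrame]
    ase_records: list
    ase_association: Optional[dict]
    direction_table: Optional[pd.DataFrame]
    report: dict = field(default_factory=dict)


def asb_table(result: PipelineResult) -> pd.DataFrame:
    """Flatten lead-SNP calls (plus feature class) into a result table."""
    rows = []
    ann = {a.snp_id: a for a in result.annotations}
    for c in result.asb.calls:
        a = ann.get(c.snp.id)
        rows.append({
            "snp_id": c.snp.id,
            "chrom_hap1": c.snp.coord_hap1.chromosome, "pos_hap1": c.snp.coord_hap1.position,
            "chrom_hap2": c.snp.coord_hap2.chromosome, "pos_hap2": c.snp.coord_hap2.position,
            "ip_count_hap1": c.snp.ip_count_hap1, "ip_count_hap2": c.snp.ip_count_hap2,
            "f_hap1": c.f_hap1, "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
            "peak_id": c.peak_id, "group_id": c.group_id,
            "n_group_members": c.n_group_members,
            "bias_pct_hap1": c.bias_pct_hap1, "direction": c.direction,
            "input_bias_stat": c.input_bias_stat,
            "passed_input_filter": c.passed_input_filter,
            "input_flag": c.input_flag or ".",
            "location_class": a.location_class if a else ".",
            "gene_id": (a.gene_id if a and a.gene_id else ".") if a else ".",
        })
    return pd.DataFrame(rows)


def cause_partition(
    asb_ids: Sequence[str],
    motif_variant_ids: set[str],
    differential_meth_ids: set[str],
    unmethylated_ids: Optional[set[str]] = None,
) -> dict:
    """Partition an ASB set by putative cause, as counts and percentages.

    ``unmethylated_ids`` (both alleles essentially unmethylated) is
    reported when provided; categories overlap (an ASB can carry both a
    motif alteration and differential methylation).
    """
    ids = list(asb_ids)
    n = len(ids)
    n_motif = sum(1 for i in ids if i in motif_variant_ids)
    n_meth = sum(1 for i in ids if i in differential_meth_ids)
    n_both = sum(1 for i in ids if i in motif_variant_ids and i in differential_meth_ids)
    out = {
        "n_asbs": n,
        "n_motif_variant": n_motif,
        "pct_motif_variant": 100.0 * n_motif / n if n else float("nan"),
        "n_differential_meth": n_meth,
        "pct_differential_meth": 100.0 * n_meth / n if n else float("nan"),
        "n_both": n_both,
        "pct_both": 100.0 * n_both / n if n else float("nan"),
    }
    if unmethylated_ids is not None:
        n_un = sum(1 for i in ids if i in unmethylated_ids)
        out["n_unmethylated"] = n_un
        out["pct_unmethylated"] = 100.0 * n_un / n if n else float("nan")
    return out


def run_pipeline(
    bundle,
    seed: int = 0,
    asb_config: Optional[AsbConfig] = None,
    bg_multiplier: float = 50.0,
    motif_flank: int = 5,
    gwas_window: int = 2000,
    enhancer_window: int = 0,
    promoter_window: int = 3000,
) -> PipelineResult:
    cfg = asb_config or AsbConfig()
    result = call_asbs(bundle.snps, bundle.peaks, cfg, seed=seed)
    report = dict(result.report)
    calls = result.calls

    # --- annotation --------------------------------------------------------
    index = annotation.GeneIndex(bundle.genes)
    anns = [annotation.classify_location(c.snp.id, c.snp.coord_hap1.chromosome,
                                         c.snp.coord_hap1.position, index)
            for c in calls]
    report["n_annotated"] = len(anns)

    # --- matched background -------------------------------------------------
    bg_sample = None
    bg_positions: list[tuple[str, int]] = []
    if calls:
        covered = coverage_filter(bundle.snps, cfg.min_each, cfg.min_one,
                                  cfg.declared_chromosomes)
        lead_ids = {c.snp.id for c in calls}
        pool = [s for s in covered if s.id not in lead_ids]
        cand = [(s.id,
                 s.coord_hap1.chromosome,
                 annotation.classify_location(s.id, s.coord_hap1.chromosome,
                                              s.coord_hap1.position, index).location_class)
                for s in pool]
        strata = [(c.snp.coord_hap1.chromosome, a.location_class)
                  for c, a in zip(calls, anns)]
        bg_sample = background.sample_background(cand, strata, multiplier=bg_multiplier,
                                                 seed=seed)
        pos_by_id = {s.id: (s.coord_hap1.chromosome, s.coord_hap1.position) for s in pool}
        bg_positions = [pos_by_id[i] for i in bg_sample.snp_ids]
        report["n_background"] = len(bg_positions)

    # --- motif variants -----------------------------------------------------
    fragments = []
    for c in calls:
        f1, f2 = c.snp.flank_hap1, c.snp.flank_hap2
        if f1 is None or f2 is None:
            continue
        high, low = (f1, f2) if c.direction == "hap1" else (f2, f1)
        h = len(high) // 2
        if h < motif_flank:
            continue
        fragments.append((c.snp.id,
                          high[h - motif_flank: h + motif_flank + 1],
                          low[h - motif_flank: h + motif_flank + 1]))
    motif_calls = motifs.scan_asb_motif_variants(fragments, motifs.BZR1_MOTIFS)
    motif_summary = {}
    for ms in motifs.BZR1_MOTIFS:
        sub = [m for m in motif_calls if m.motif_name == ms.name]
        motif_summary[ms.name] = motifs.canonical_bias_fraction(sub)
    informative_ids = {m.snp_id for m in motif_calls if m.classification != "uninformative"}
    report["n_motif_variant_asbs"] = len(informative_ids)

    # --- methylation --------------------------------------------------------
    meth_calls: dict[str, list] = {}
    for context in ("CG", "CHG", "CHH"):
        t1 = bundle.methylation.get(("hap1", context))
        t2 = bundle.methylation.get(("hap2", context))
        if t1 is None or t2 is None:
            continue
        loci = [(c.snp.id, c.snp.coord_hap1.chromosome, c.snp.coord_hap1.position,
                 c.snp.coord_hap2.chromosome, c.snp.coord_hap2.position)
                for c in calls]
        meth_calls[context] = methylation.methylation_at_asbs(loci, t1, t2)
    report["n_differential_meth"] = {
        ctx: sum(m.differential for m in v) for ctx, v in meth_calls.items()}

    # --- enrichment ---------------------------------------------------------
    enh_res = None
    gwas_df = None
    if calls and bg_positions:
        q_pos = [(c.snp.coord_hap1.chromosome, c.snp.coord_hap1.position) for c in calls]
        if bundle.enhancers:
            qh = int(enrichment.proximity_hits(q_pos, bundle.enhancers, enhancer_window).sum())
            bh = int(enrichment.proximity_hits(bg_positions, bundle.enhancers,
                                               enhancer_window).sum())
            enh_res = enrichment.hypergeometric_enrichment(
                qh, len(q_pos), bh, len(bg_positions),
                feature_set_name="enhancers", window_bp=enhancer_window)
        if bundle.gwas is not None and len(bundle.gwas):
            gwas_df = enrichment.per_trait_enrichment(q_pos, bg_positions, bundle.gwas,
                                                      window_bp=gwas_window)

    # --- ASE linkage --------------------------------------------------------
    ase_records: list = []
    ase_assoc = None
    direction_tab = None
    if bundle.expression is not None and len(bundle.expression):
        ase_records = ase.call_ase(bundle.expression)
        promoter_genes: dict[str, str] = {}
        for c in calls:
            for hit in annotation.assign_target_genes(
                    c.snp.coord_hap1.chromosome, c.snp.coord_hap1.position, index,
                    promoter=promoter_window):
                if hit["in_promoter"]:
                    promoter_genes.setdefault(hit["gene_id"], c.direction)
        if promoter_genes:
            ase_assoc = ase.asb_ase_association(ase_records, promoter_genes)
            pairs = []
            for r in ase_records:
                if r.gene_id in promoter_genes and r.as_biased:
                    expr_dir = "hap1" if r.fold_change >= 1.0 else "hap2"
                    pairs.append((promoter_genes[r.gene_id], expr_dir))
            if pairs:
                direction_tab = ase.direction_concordance(pairs)
        report["n_ase_pass"] = sum(r.passes_filters for r in ase_records)
        report["n_ase_biased"] = sum(r.as_biased for r in ase_records)
        report["n_asb_promoter_genes"] = len(promoter_genes)

    return PipelineResult(
        asb=result, annotations=anns, background=bg_sample,
        motif_calls=motif_calls, motif_summary=motif_summary,
        methylation_calls=meth_calls,
        enhancer_enrichment=enh_res, gwas_enrichment=gwas_df,
        ase_records=ase_records, ase_association=ase_assoc,
        direction_table=direction_tab, report=report)
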