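"""Allele-specific expression (ASE) calling and linkage to ASBs.

Genes pass the read filters when their pooled allelic counts total at
least 20 with at least one read per allele; a gene is allele-biased when
its allele fold change reaches 1.5 in either direction.  The association
between ASBs in promoters and ASE is a 2x2 Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

MIN_TOTAL_READS = 20
MIN_PER_ALLELE = 1
FOLD_CUTOFF = 1.5


@dataclass
class AseRecord:
    gene_id: str
    reads_hap1: int
    reads_hap2: int
    fold_change: float          # hap1 / hap2 orientation (inf if hap2 == 0)
    passes_filters: bool
    as_biased: bool


def _fold(reads1: float, reads2: float) -> float:
    if reads2 == 0:
        return float("inf") if reads1 > 0 else float("nan")
    return reads1 / reads2


def call_ase(expression: pd.DataFrame) -> list[AseRecord]:
    """Apply the ASE read filters and fold-change rule to a count table.

    With per-replicate columns (``reads_hap1_r<i>``/``reads_hap2_r<i>``)
    the fold change is computed per replicate and averaged over replicates
    where both alleles are covered; the filters apply to pooled counts.
    """
    if "gene_id" not in expression.columns:
        raise ConfigError("expression table needs a 'gene_id' column")
    rep_pairs = []
    for col in expression.columns:
        if col.startswith("reads_hap1_r"):
            suffix = col[len("reads_hap1_r"):]
            partner = f"reads_hap2_r{suffix}"
            if partner in expression.columns:
                rep_pairs.append((col, partner))
    pooled = ("reads_hap1" in expression.columns and "reads_hap2" in expression.columns)
    if not rep_pairs and not pooled:
        raise ConfigError("expression table needs pooled or per-replicate read columns")

    out: list[AseRecord] = []
    for row in expression.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(expression.columns, row))
        if rep_pairs:
            r1 = sum(int(d[a]) for a, _ in rep_pairs)
            r2 = sum(int(d[b]) for _, b in rep_pairs)
            fcs = [_fold(int(d[a]), int(d[b])) for a, b in rep_pairs
                   if int(d[a]) > 0 and int(d[b]) > 0]
            fc = float(np.mean(fcs)) if fcs else _fold(r1, r2)
        else:
            r1, r2 = int(d["reads_hap1"]), int(d["reads_hap2"])
            fc = _fold(r1, r2)
        passes = (r1 + r2 >= MIN_TOTAL_READS and min(r1, r2) >= MIN_PER_ALLELE)
        biased = bool(passes and np.isfinite(fc) and fc > 0
                      and max(fc, 1.0 / fc) >= FOLD_CUTOFF)
        out.append(AseRecord(d["gene_id"], r1, r2, fc, passes, biased))
    return out


def association_from_counts(
    asb_biased: int, asb_total: int, other_biased: int, other_total: int
) -> dict:
    """Proportions and two-sided Fisher exact test for a 2x2 table of
    (ASB-promoter vs other genes) x (allele-biased vs not)."""
    table = [[asb_biased, asb_total - asb_biased],
             [other_biased, other_total - other_biased]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "n_asb_genes": asb_total,
        "n_asb_biased": asb_biased,
        "prop_asb": asb_biased / asb_total if asb_total else float("nan"),
        "n_other_genes": other_total,
        "n_other_biased": other_biased,
        "prop_other": other_biased / other_total if other_total else float("nan"),
        "odds_ratio": float(odds),
        "p_value": float(p),
    }


def asb_ase_association(
    records: Sequence[AseRecord], asb_promoter_genes: Iterable[str]
) -> dict:
    """Compare the ASE rate of genes with an ASB in their promoter against
    the remaining filter-passing genes."""
    promoter = set(asb_promoter_genes)
    passing = [r for r in records if r.passes_filters]
    asb = [r for r in passing if r.gene_id in promoter]
    other = [r for r in passing if r.gene_id not in promoter]
    return association_from_counts(
        sum(r.as_biased for r in asb), len(asb),
        sum(r.as_biased for r in other), len(other))


def direction_concordance(
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """2x2 cross-tabulation of binding-bias direction vs expression-bias
    direction over (binding_direction, expression_direction) pairs, each
    'hap1' or 'hap2'.  Descriptive only — no causal claim."""
    df = pd.DataFrame(pairs, columns=["binding", "expression"])
    tab = pd.crosstab(df["binding"], df["expression"])
    for lab in ("hap1", "hap2"):
        if lab not in tab.index:
            tab.loc[lab] = 0
        if lab not in tab.columns:
            tab[lab] = 0
    return tab.loc[["hap1", "hap2"], ["hap1", "hap2"]]
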