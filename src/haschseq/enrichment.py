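"""Proximity enrichment of ASBs versus matched background SNPs.

A variant "hits" a feature set when any feature (point or interval) lies
within a fixed window of it; enrichment of the hit rate in the query set
over the matched background is tested with an upper-tail hypergeometric
test on the pooled urn (query + background variants, hits as successes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsError
from .models import GenomicInterval


@dataclass
class EnrichmentResult:
    feature_set_name: str
    window_bp: int
    n_query_hit: int
    n_query: int
    n_bg_hit: int
    n_bg: int
    fold: float
    p_value: float


def proximity_hits(
    variants: Sequence[tuple[str, int]],
    features: Sequence[GenomicInterval],
    window_bp: int,
) -> np.ndarray:
    """Boolean hit flag per variant: any feature within ``window_bp``.

    ``variants`` are (chromosome, position) pairs; the distance to an
    interval is 0 when the position lies inside it (half-open).
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {f.chromosome for f in features}:
        sub = sorted((f for f in features if f.chromosome == chrom), key=lambda f: f.start)
        starts[chrom] = np.array([f.start for f in sub])
        ends[chrom] = np.array([f.end for f in sub])

    hits = np.zeros(len(variants), dtype=bool)
    for i, (chrom, pos) in enumerate(variants):
        if chrom not in starts:
            continue
        s, e = starts[chrom], ends[chrom]
        # distance to [s, e): 0 inside, else gap to the nearest edge;
        # starts are sorted, so scanning can stop once s[k] > pos + window
        best = np.inf
        for k in range(len(s)):
            if s[k] - pos > window_bp and s[k] > pos:
                break
            d = 0 if s[k] <= pos < e[k] else min(abs(pos - s[k]), abs(pos - (e[k] - 1)))
            best = min(best, d)
        hits[i] = best <= window_bp
    return hits


def hypergeometric_enrichment(
    n_query_hit: int,
    n_query: int,
    n_bg_hit: int,
    n_bg: int,
    feature_set_name: str = "features",
    window_bp: int = 0,
    method: str = "hypergeometric",
) -> EnrichmentResult:
    """Fold enrichment and upper-tail p-value of query hits vs background.

    The urn pools query and background variants (``n_query + n_bg`` balls,
    ``n_query_hit + n_bg_hit`` successes); the p-value is the probability
    of drawing at least ``n_query_hit`` successes in ``n_query`` draws.
    ``method='fisher'`` uses the one-sided Fisher exact test instead
    (equivalent tail, different conditioning presentation).
    """
    if n_query_hit > n_query or n_bg_hit > n_bg:
        raise StatisticsError("hit counts exceed set sizes")
    if n_query == 0 or n_bg == 0:
        raise StatisticsError("empty query or background set")
    q_rate = n_query_hit / n_query
    b_rate = n_bg_hit / n_bg
    if n_query_hit == 0:
        fold, p = 0.0, 1.0
    elif n_bg_hit == 0:
        fold, p = float("inf"), _upper_tail(n_query_hit, n_query, n_bg_hit, n_bg, method)
    else:
        fold = q_rate / b_rate
        p = _upper_tail(n_query_hit, n_query, n_bg_hit, n_bg, method)
    return EnrichmentResult(feature_set_name, window_bp, n_query_hit, n_query,
                            n_bg_hit, n_bg, fold, p)


def _upper_tail(qh: int, q: int, bh: int, b: int, method: str) -> float:
    if method == "fisher":
        _, p = stats.fisher_exact([[qh, q - qh], [bh, b - bh]], alternative="greater")
        return float(p)
    M, K, n = q + b, qh + bh, q
    return float(stats.hypergeom.sf(qh - 1, M, K, n))


def per_trait_enrichment(
    variants: Sequence[tuple[str, int]],
    bg_variants: Sequence[tuple[str, int]],
    catalog: pd.DataFrame,
    window_bp: int = 2000,
    trait_column: str = "trait",
) -> pd.DataFrame:
    """One enrichment row per trait of a GWAS catalog.

    ``catalog`` needs columns ``chromosome``, ``position`` (hits treated
    as points) and the trait column.  Unadjusted p-values are reported
    alongside a Benjamini-Hochberg column.
    """
    rows = []
    for trait, sub in catalog.groupby(trait_column):
        feats = [GenomicInterval(r.chromosome, int(r.position), int(r.position) + 1, str(trait))
                 for r in sub.itertuples()]
        if not feats:
            rows.append({"trait": trait, "n_features": 0, "n_query_hit": 0,
                         "n_query": len(variants), "n_bg_hit": 0,
                         "n_bg": len(bg_variants), "fold": float("nan"),
                         "p_value": 1.0})
            continue
        qh = int(proximity_hits(variants, feats, window_bp).sum())
        bh = int(proximity_hits(bg_variants, feats, window_bp).sum())
        res = hypergeometric_enrichment(qh, len(variants), bh, len(bg_variants),
                                        feature_set_name=str(trait), window_bp=window_bp)
        rows.append({"trait": trait, "n_features": len(feats),
                     "n_query_hit": res.n_query_hit, "n_query": res.n_query,
                     "n_bg_hit": res.n_bg_hit, "n_bg": res.n_bg,
                     "fold": res.fold, "p_value": res.p_value})
    df = pd.DataFrame(rows)
    if len(df):
        from statsmodels.stats.multitest import multipletests

        _, p_bh, _, _ = multipletests(df["p_value"].fillna(1.0), method="fdr_bh")
        df["p_bh"] = p_bh
    return df


def hit_density_profile(
    variants: Sequence[tuple[str, int]],
    features: Sequence[GenomicInterval],
    span: int = 10000,
    bin_size: int = 500,
) -> pd.DataFrame:
    """Counts of variants per distance bin around feature midpoints;
    integrates to the number of (variant, nearest-feature) pairs in range."""
    mids: dict[str, np.ndarray] = {}
    for chrom in {f.chromosome for f in features}:
        sub = [f for f in features if f.chromosome == chrom]
        mids[chrom] = np.sort(np.array([(f.start + f.end) // 2 for f in sub]))
    n_bins = 2 * span // bin_size
    counts = np.zeros(n_bins, dtype=int)
    for chrom, pos in variants:
        m = mids.get(chrom)
        if m is None or not len(m):
            continue
        j = np.searchsorted(m, pos)
        cands = [m[k] for k in (j - 1, j) if 0 <= k < len(m)]
        if not cands:
            continue
        nearest = min(cands, key=lambda c: abs(pos - c))
        d = pos - nearest
        if -span <= d < span:
            counts[(d + span) // bin_size] += 1
    return pd.DataFrame({
        "bin_start_offset": np.arange(n_bins) * bin_size - span,
        "n_variants": counts,
    })
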