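"""Matched background SNP (bgSNP) sampling.

Control SNPs for enrichment tests are drawn from the covered heterozygous
SNP pool (excluding ASBs) so that, per chromosome and genomic feature
class, the background contains ``multiplier`` times as many SNPs as the
ASB set — and, optionally, so that its minor-allele-frequency histogram
matches the ASB set's within binned acceptance sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import StatisticsError


@dataclass
class BackgroundSample:
    """Outcome of stratified background sampling."""

    snp_ids: list[str]
    strata: dict = field(default_factory=dict)          # (chrom, class) -> dict
    shortfalls: list[tuple[str, str, int, int]] = field(default_factory=list)


def sample_background(
    candidates: Sequence[tuple[str, str, str]],
    asb_strata: Sequence[tuple[str, str]],
    multiplier: float = 50.0,
    maf: Optional[dict[str, float]] = None,
    asb_maf: Optional[Sequence[float]] = None,
    maf_bins: int = 10,
    seed: int = 0,
) -> BackgroundSample:
    """Sample background SNPs matched per (chromosome x location class).

    Parameters
    ----------
    candidates
        (snp_id, chromosome, location_class) triples for the eligible pool;
        the caller must already have excluded ASBs.
    asb_strata
        (chromosome, location_class) pairs, one per ASB; the per-stratum
        target is ``multiplier`` times the ASB count in that stratum.
    maf, asb_maf
        When both are given, sampling within each stratum is additionally
        stratified over ``maf_bins`` equal-width bins on [0, 0.5] so the
        background MAF histogram tracks the ASB histogram.
    """
    rng = np.random.default_rng(seed)
    targets: dict[tuple[str, str], int] = {}
    for chrom, cls in asb_strata:
        targets[(chrom, cls)] = targets.get((chrom, cls), 0) + 1
    targets = {k: int(round(multiplier * v)) for k, v in targets.items()}

    pool: dict[tuple[str, str], list[str]] = {}
    for sid, chrom, cls in candidates:
        pool.setdefault((chrom, cls), []).append(sid)

    asb_maf_by_stratum: dict[tuple[str, str], list[float]] = {}
    if maf is not None and asb_maf is not None:
        for (chrom, cls), m in zip(asb_strata, asb_maf):
            asb_maf_by_stratum.setdefault((chrom, cls), []).append(m)

    edges = np.linspace(0.0, 0.5, maf_bins + 1)

    def _bin(value: float) -> int:
        return int(min(np.searchsorted(edges, value, side="right") - 1, maf_bins - 1))

    out = BackgroundSample(snp_ids=[])
    for key in sorted(targets):
        target = targets[key]
        avail = pool.get(key, [])
        chosen: list[str]
        if maf is not None and asb_maf is not None and avail:
            # acceptance within MAF bins proportional to the ASB histogram
            want_hist = np.zeros(maf_bins, dtype=float)
            for m in asb_maf_by_stratum.get(key, []):
                want_hist[_bin(m)] += 1
            if want_hist.sum() == 0:
                want_hist[:] = 1
            want = want_hist / want_hist.sum() * target
            chosen = []
            by_bin: dict[int, list[str]] = {}
            for sid in avail:
                by_bin.setdefault(_bin(maf.get(sid, 0.25)), []).append(sid)
            for b in range(maf_bins):
                take = int(round(want[b]))
                bucket = by_bin.get(b, [])
                take = min(take, len(bucket))
                if take:
                    idx = rng.choice(len(bucket), size=take, replace=False)
                    chosen.extend(bucket[i] for i in sorted(idx))
        else:
            take = min(target, len(avail))
            if take:
                idx = rng.choice(len(avail), size=take, replace=False)
                chosen = [avail[i] for i in sorted(idx)]
            else:
                chosen = []
        if len(chosen) < target:
            out.shortfalls.append((key[0], key[1], target, len(chosen)))
        out.strata[key] = {"target": target, "pool": len(avail), "sampled": len(chosen)}
        out.snp_ids.extend(chosen)

    if len(set(out.snp_ids)) != len(out.snp_ids):
        raise StatisticsError("background sampling produced duplicate SNP ids")
    return out
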