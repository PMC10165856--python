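"""Haplotype-specific DNA methylation at ASB loci.

Methylation levels are computed per haplotype in a small window around
each ASB (each haplotype's window on its own coordinate system), the
differential rule classifies loci where one allele is >= 70% methylated
while the other is <= 10%, and affinity-stratified metaprofiles average
methylation in 10-bp bins up to +/- 2 kb around ASBs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsError
from .models import MethylationTrack

DIFFERENTIAL_HIGH = 0.70
DIFFERENTIAL_LOW = 0.10


@dataclass
class AsbMethylation:
    snp_id: str
    context: str
    level_hap1: Optional[float]             # None when no covered cytosines
    level_hap2: Optional[float]
    differential: bool
    hypomethylated_allele: str              # "hap1", "hap2", "none"


def _window_level(
    track: MethylationTrack,
    chromosome: str,
    center: int,
    half_window: int,
    mode: str,
    min_cytosines: int,
) -> Optional[float]:
    start, end = center - half_window, center + half_window + 1
    if mode == "pooled":
        meth, total = track.window_counts(chromosome, start, end)
        if total == 0:
            return None
        covered = track.window_fractions(chromosome, start, end)
        if len(covered) < min_cytosines:
            return None
        return meth / total
    elif mode == "per_cytosine":
        frac = track.window_fractions(chromosome, start, end)
        if len(frac) < min_cytosines:
            return None
        return float(frac["fraction"].mean())
    raise ValueError(f"unknown level mode {mode!r}")


def classify_differential(level_hap1: Optional[float], level_hap2: Optional[float]) -> tuple[bool, str]:
    """Apply the >=70% / <=10% differential-methylation rule (symmetric)."""
    if level_hap1 is None or level_hap2 is None:
        return False, "none"
    if level_hap1 >= DIFFERENTIAL_HIGH and level_hap2 <= DIFFERENTIAL_LOW:
        return True, "hap2"
    if level_hap2 >= DIFFERENTIAL_HIGH and level_hap1 <= DIFFERENTIAL_LOW:
        return True, "hap1"
    return False, "none"


def methylation_at_asbs(
    loci: Sequence[tuple[str, str, int, str, int]],
    track_hap1: MethylationTrack,
    track_hap2: MethylationTrack,
    half_window: int = 20,
    mode: str = "pooled",
    min_cytosines: int = 1,
) -> list[AsbMethylation]:
    """Per-ASB methylation levels on both haplotypes and differential calls.

    ``loci`` holds (snp_id, chrom_hap1, pos_hap1, chrom_hap2, pos_hap2):
    each haplotype's window is taken on its own coordinates.  ``mode``
    selects pooled-read weighting (default) or per-cytosine fraction means.
    """
    if track_hap1.context != track_hap2.context:
        raise StatisticsError("haplotype tracks have different contexts")
    out = []
    for snp_id, c1, p1, c2, p2 in loci:
        l1 = _window_level(track_hap1, c1, p1, half_window, mode, min_cytosines)
        l2 = _window_level(track_hap2, c2, p2, half_window, mode, min_cytosines)
        diff, hypo = classify_differential(l1, l2)
        out.append(AsbMethylation(snp_id, track_hap1.context, l1, l2, diff, hypo))
    return out


def methylation_metaprofile(
    loci: Sequence[tuple[str, str, int, str, int, float]],
    track_hap1: MethylationTrack,
    track_hap2: MethylationTrack,
    span: int = 2000,
    bin_size: int = 10,
    high_cut: float = 85.0,
    low_cut: float = 15.0,
) -> pd.DataFrame:
    """Affinity-stratified methylation metaprofile around ASBs.

    ``loci`` holds (snp_id, chrom_hap1, pos_hap1, chrom_hap2, pos_hap2,
    bias_pct_hap1).  ASBs with bias percentage >= ``high_cut`` form the
    hap1-high stratum (hap1 is the high-affinity allele there, hap2 low);
    <= ``low_cut`` the converse.  Per 10-bp bin, methylation is the
    coverage-weighted mean over pooled reads of all contributing loci;
    bins with no covered cytosines are NaN.
    """
    n_bins = 2 * span // bin_size
    offsets = np.arange(n_bins) * bin_size - span  # bin start offsets
    groups = {
        "hap1_high": np.zeros((n_bins, 2)),  # columns: methylated, total
        "hap1_low": np.zeros((n_bins, 2)),
        "hap2_high": np.zeros((n_bins, 2)),
        "hap2_low": np.zeros((n_bins, 2)),
    }
    counts = {"hap1_high": 0, "hap1_low": 0, "hap2_high": 0, "hap2_low": 0}

    def _accumulate(acc: np.ndarray, track: MethylationTrack, chrom: str, center: int) -> None:
        sub = track.window_fractions(chrom, center - span, center + span)
        if not len(sub):
            return
        rel = sub["position"].to_numpy() - center
        b = np.clip((rel + span) // bin_size, 0, n_bins - 1).astype(int)
        np.add.at(acc[:, 0], b, sub["methylated"].to_numpy())
        np.add.at(acc[:, 1], b, sub["total"].to_numpy())

    for snp_id, c1, p1, c2, p2, bias_pct in loci:
        if bias_pct >= high_cut:
            hap1_group, hap2_group = "hap1_high", "hap2_low"
        elif bias_pct <= low_cut:
            hap1_group, hap2_group = "hap1_low", "hap2_high"
        else:
            continue
        counts[hap1_group] += 1
        counts[hap2_group] += 1
        _accumulate(groups[hap1_group], track_hap1, c1, p1)
        _accumulate(groups[hap2_group], track_hap2, c2, p2)

    data = {"bin_start_offset": offsets}
    for name, acc in groups.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            data[name] = np.where(acc[:, 1] > 0, acc[:, 0] / np.maximum(acc[:, 1], 1), np.nan)
    df = pd.DataFrame(data)
    df.attrs["n_loci"] = counts
    df.attrs["context"] = track_hap1.context
    return df


def hypo_binding_concordance(
    meth_calls: Sequence[AsbMethylation],
    direction_by_id: dict[str, str],
) -> dict:
    """Among differentially methylated ASBs, the fraction whose
    hypomethylated allele is the higher-binding allele (CG/CHG methylation
    represses binding, so concordance is the expected direction)."""
    considered = [m for m in meth_calls
                  if m.differential and m.snp_id in direction_by_id]
    n = len(considered)
    k = sum(1 for m in considered if m.hypomethylated_allele == direction_by_id[m.snp_id])
    return {"n_differential": n, "n_concordant": k,
            "fraction": k / n if n else float("nan")}


def inbred_f1_concordance(
    diffs_a: Sequence[tuple[str, float]],
    diffs_b: Sequence[tuple[str, float]],
) -> dict:
    """Pearson correlation of per-ASB methylation differences
    (level_hap1 - level_hap2) between two datasets (e.g. F1 vs parents),
    over ASBs defined in both."""
    a = dict(diffs_a)
    b = dict(diffs_b)
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise StatisticsError(f"only {len(shared)} shared loci; need >= 3 for a correlation")
    x = np.array([a[s] for s in shared])
    y = np.array([b[s] for s in shared])
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n": len(shared)}
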