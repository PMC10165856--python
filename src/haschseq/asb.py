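"""Allele-specific binding (ASB) calling.

The calling funnel mirrors the standard allelic-imbalance workflow for
F1-hybrid ChIP-seq: a read-coverage filter on heterozygous SNPs, an exact
two-sided binomial test of each SNP's IP allele frequency against the
genome-wide null frequency, Bonferroni correction over the tested family,
restriction to SNPs inside high-confidence binding peaks, single-linkage
grouping of nearby significant SNPs (reads spanning ~200 bp make linked
SNPs co-significant), selection of the group member nearest the peak summit
as the lead SNP, and finally an empirical input-bias exclusion filter that
flags leads whose surrounding ChIP-input allele fraction is extreme
relative to matched background loci (mapping/copy-number artifacts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .errors import InputError, StatisticsError
from .models import Peak, SnpRecord

#: relative tolerance for probability-mass ties in the two-sided test
#: (same convention as R's binom.test)
_TIE_RTOL = 1e-7


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def coverage_filter(
    snps: Sequence[SnpRecord],
    min_each: int = 1,
    min_one: int = 25,
    declared_chromosomes: Optional[set[str]] = None,
) -> list[SnpRecord]:
    """Keep SNPs with both IP allele counts >= ``min_each`` and the larger
    one >= ``min_one``; SNPs on undeclared scaffolds are dropped."""
    out = []
    for s in snps:
        if declared_chromosomes is not None and s.coord_hap1.chromosome not in declared_chromosomes:
            continue
        lo = min(s.ip_count_hap1, s.ip_count_hap2)
        hi = max(s.ip_count_hap1, s.ip_count_hap2)
        if lo >= min_each and hi >= min_one:
            out.append(s)
    return out


def estimate_null_frequency(snps: Sequence[SnpRecord]) -> float:
    """Median IP allele frequency of haplotype 1 over covered SNPs.

    Used as the binomial null probability; absorbs residual global mapping
    bias between the two haplotype assemblies.
    """
    if not snps:
        raise StatisticsError("cannot estimate null allele frequency from zero SNPs")
    freqs = np.array([s.f_hap1 for s in snps], dtype=float)
    return float(np.median(freqs))


def binomial_bias_test(k: int, n: int, p_null: float) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood definition).

    Sums Binomial(n, p_null) probabilities over all outcomes whose
    probability mass does not exceed that of the observed ``k`` (within a
    small relative tolerance for ties) — the appropriate two-sided test
    when ``p_null`` is not 0.5 and the distribution is asymmetric.
    """
    if not (0 <= k <= n) or n < 1:
        raise InputError(f"invalid binomial test arguments k={k}, n={n}")
    if not (0.0 < p_null < 1.0):
        raise InputError(f"p_null must be in (0,1), got {p_null}")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p_null)
    p = pmf[pmf <= pmf[k] * (1.0 + _TIE_RTOL)].sum()
    return float(min(1.0, p))


def binomial_bias_test_many(ks: np.ndarray, ns: np.ndarray, p_null: float) -> np.ndarray:
    """Vectorised :func:`binomial_bias_test` over SNP arrays (grouped by n)."""
    ks = np.asarray(ks, dtype=int)
    ns = np.asarray(ns, dtype=int)
    out = np.empty(len(ks), dtype=float)
    for n in np.unique(ns):
        idx = np.nonzero(ns == n)[0]
        pmf = stats.binom.pmf(np.arange(n + 1), int(n), p_null)
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        # p(k) = sum of pmf over outcomes with pmf <= pmf[k]*(1+tol)
        thresh = pmf[ks[idx]] * (1.0 + _TIE_RTOL)
        sorted_pmf = pmf[order]
        ranks = np.searchsorted(sorted_pmf, thresh, side="right")
        vals = np.where(ranks > 0, csum[np.maximum(ranks - 1, 0)], 0.0)
        out[idx] = np.minimum(1.0, vals)
    return out


def bonferroni_adjust(p_values: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni adjustment over a declared family of ``m`` tests."""
    p_values = np.asarray(p_values, dtype=float)
    if m < len(p_values):
        raise InputError(f"family size m={m} smaller than number of p-values {len(p_values)}")
    return np.minimum(1.0, p_values * m)


# ---------------------------------------------------------------------------
# peaks, linkage groups, lead SNPs
# ---------------------------------------------------------------------------

def restrict_to_peaks(
    snps: Sequence[SnpRecord], peaks: Sequence[Peak]
) -> list[tuple[SnpRecord, str]]:
    """Keep SNPs whose reference-haplotype position lies inside a peak.

    A SNP overlapped by several peaks is assigned to the peak whose summit
    is nearest (the lead-SNP rule needs a unique summit).
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {p.peak_id: p for p in peaks}
    for p in peaks:
        trees.setdefault(p.chromosome, IntervalTree()).addi(p.start, p.end, p.peak_id)
    out: list[tuple[SnpRecord, str]] = []
    for s in snps:
        tree = trees.get(s.coord_hap1.chromosome)
        if tree is None:
            continue
        pos = s.coord_hap1.position
        hits = tree[pos]
        if not hits:
            continue
        best = min(hits, key=lambda iv: (abs(pos - by_id[iv.data].summit), by_id[iv.data].start,
                                         by_id[iv.data].peak_id))
        out.append((s, best.data))
    return out


def build_linkage_groups(positions: Sequence[int], window: int = 150) -> list[list[int]]:
    """Partition sorted positions into maximal single-linkage chains.

    Two positions belong to the same group iff a chain of consecutive
    member pairs, each at most ``window`` bp apart, connects them.
    Returns groups as lists of indices into the (sorted) input order.
    """
    if len(positions) == 0:
        return []
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    groups: list[list[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if positions[cur] - positions[prev] <= window:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    return groups


def select_lead_snp(
    members: Sequence[tuple[int, str]], summit: int
) -> str:
    """Pick the group member nearest the peak summit.

    ``members`` is a sequence of (position, snp_id).  Ties are broken by
    smaller genomic position, then lexicographic id.
    """
    if not members:
        raise InputError("cannot select a lead SNP from an empty group")
    return min(members, key=lambda m: (abs(m[0] - summit), m[0], m[1]))[1]


# ---------------------------------------------------------------------------
# input-bias exclusion filter
# ---------------------------------------------------------------------------

def _pooled_input_fraction(
    positions: np.ndarray,
    input1: np.ndarray,
    input_total: np.ndarray,
    center: int,
    half_window: int,
) -> float:
    """Pooled hap1 input-read fraction over SNPs within +/- half_window.

    Returns NaN when no input reads fall in the window.
    """
    lo = positions.searchsorted(center - half_window, side="left")
    hi = positions.searchsorted(center + half_window, side="right")
    tot = input_total[lo:hi].sum()
    if tot == 0:
        return float("nan")
    return float(input1[lo:hi].sum() / tot)


def input_bias_filter(
    candidates: Sequence[SnpRecord],
    all_snps: Sequence[SnpRecord],
    background_snps: Sequence[SnpRecord],
    half_window: int = 1000,
    alpha_percentile: float = 5.0,
    min_background: int = 50,
) -> list[dict]:
    """Flag candidate ASBs whose local input allele fraction is extreme.

    For each candidate the statistic is the count-weighted hap1 fraction of
    ChIP-input reads pooled over all SNPs within ``half_window`` of the lead
    position.  The empirical null is the same statistic at background SNPs;
    candidates strictly beyond the ``alpha_percentile``-th or
    ``(100 - alpha_percentile)``-th percentile fail.  Candidates with no
    input coverage in the window pass with flag ``no-input-coverage`` —
    the filter is an exclusion test and absence of evidence is not bias.
    """
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {s.coord_hap1.chromosome for s in all_snps}:
        rows = sorted(
            (s for s in all_snps if s.coord_hap1.chromosome == chrom),
            key=lambda s: s.coord_hap1.position,
        )
        per_chrom[chrom] = (
            np.array([s.coord_hap1.position for s in rows]),
            np.array([s.input_count_hap1 for s in rows]),
            np.array([s.input_count_hap1 + s.input_count_hap2 for s in rows]),
        )

    def stat(snp: SnpRecord) -> float:
        arrs = per_chrom.get(snp.coord_hap1.chromosome)
        if arrs is None:
            return float("nan")
        return _pooled_input_fraction(*arrs, snp.coord_hap1.position, half_window)

    null = np.array([stat(s) for s in background_snps], dtype=float)
    null = null[~np.isnan(null)]
    if len(null) < min_background:
        raise StatisticsError(
            f"only {len(null)} background input-fraction observations; "
            f"need >= {min_background} to estimate the empirical null")
    lo, hi = np.percentile(null, [alpha_percentile, 100.0 - alpha_percentile])

    out = []
    for c in candidates:
        s = stat(c)
        if math.isnan(s):
            out.append({"snp_id": c.id, "input_bias_stat": float("nan"),
                        "passed_input_filter": True, "input_flag": "no-input-coverage"})
        else:
            passed = bool(lo <= s <= hi)
            out.append({"snp_id": c.id, "input_bias_stat": s,
                        "passed_input_filter": passed, "input_flag": ""})
    return out


# ---------------------------------------------------------------------------
# the full funnel
# ---------------------------------------------------------------------------

@dataclass
class AsbConfig:
    """Tunable thresholds of the calling funnel (defaults follow the
    standard HASCh-seq settings)."""

    min_each: int = 1
    min_one: int = 25
    alpha: float = 0.001
    p_null: Optional[float] = None          # None -> observed median
    linkage_window: int = 150
    input_half_window: int = 1000
    input_percentile: float = 5.0
    min_background_obs: int = 50
    background_per_candidate: int = 10      # per-chromosome null sample size factor
    declared_chromosomes: Optional[set[str]] = None
    apply_input_filter: bool = True


@dataclass
class AsbCall:
    """A lead SNP passing the significance funnel, with bias statistics."""

    snp: SnpRecord
    peak_id: str
    group_id: str
    n_group_members: int
    f_hap1: float
    p_raw: float
    p_adjusted: float
    bias_pct_hap1: float
    direction: str                          # "hap1" or "hap2"
    input_bias_stat: float = float("nan")
    passed_input_filter: bool = True
    input_flag: str = ""


@dataclass
class AsbResult:
    calls: list[AsbCall]
    p_null: float
    report: dict = field(default_factory=dict)

    @property
    def final_calls(self) -> list[AsbCall]:
        """Calls surviving the input-bias exclusion."""
        return [c for c in self.calls if c.passed_input_filter]


def call_asbs(
    snps: Sequence[SnpRecord],
    peaks: Sequence[Peak],
    config: Optional[AsbConfig] = None,
    seed: int = 0,
) -> AsbResult:
    """Run the full ASB-calling funnel; deterministic given inputs and seed.

    The seed only affects the per-chromosome background sample used for the
    empirical input-bias null.
    """
    cfg = config or AsbConfig()
    report: dict = {"n_input_snps": len(snps)}

    covered = coverage_filter(snps, cfg.min_each, cfg.min_one, cfg.declared_chromosomes)
    report["n_covered"] = len(covered)
    if not covered:
        report["n_significant"] = report["n_in_peaks"] = 0
        report["n_linkage_groups"] = report["n_leads"] = report["n_final"] = 0
        return AsbResult(calls=[], p_null=float("nan"), report=report)

    p_null = cfg.p_null if cfg.p_null is not None else estimate_null_frequency(covered)
    report["p_null"] = p_null

    ks = np.array([s.ip_count_hap1 for s in covered])
    ns = np.array([s.ip_total for s in covered])
    p_raw = binomial_bias_test_many(ks, ns, p_null)
    p_adj = bonferroni_adjust(p_raw, m=len(covered))
    sig_mask = p_adj <= cfg.alpha
    significant = [s for s, keep in zip(covered, sig_mask) if keep]
    pvals = {s.id: (float(pr), float(pa)) for s, pr, pa in zip(covered, p_raw, p_adj)}
    report["n_significant"] = len(significant)

    in_peaks = restrict_to_peaks(significant, peaks)
    report["n_in_peaks"] = len(in_peaks)

    # group per peak, then chain by the linkage window
    by_peak: dict[str, list[SnpRecord]] = {}
    for s, pid in in_peaks:
        by_peak.setdefault(pid, []).append(s)
    peak_by_id = {p.peak_id: p for p in peaks}

    calls: list[AsbCall] = []
    n_groups = 0
    for pid in sorted(by_peak):
        members = sorted(by_peak[pid], key=lambda s: s.coord_hap1.position)
        positions = [s.coord_hap1.position for s in members]
        groups = build_linkage_groups(positions, cfg.linkage_window)
        summit = peak_by_id[pid].summit
        for gi, idxs in enumerate(groups):
            n_groups += 1
            group_members = [(members[i].coord_hap1.position, members[i].id) for i in idxs]
            lead_id = select_lead_snp(group_members, summit)
            lead = next(members[i] for i in idxs if members[i].id == lead_id)
            f = lead.f_hap1
            pr, pa = pvals[lead.id]
            calls.append(AsbCall(
                snp=lead, peak_id=pid, group_id=f"{pid}.g{gi}",
                n_group_members=len(idxs), f_hap1=f, p_raw=pr, p_adjusted=pa,
                bias_pct_hap1=100.0 * f,
                direction="hap1" if f > p_null else "hap2",
            ))
    report["n_linkage_groups"] = n_groups
    report["n_leads"] = len(calls)

    if cfg.apply_input_filter and calls:
        lead_ids = {c.snp.id for c in calls}
        pool = [s for s in covered if s.id not in lead_ids]
        rng = np.random.default_rng(seed)
        n_bg = min(len(pool), max(cfg.min_background_obs,
                                  cfg.background_per_candidate * len(calls)))
        # proportional per-chromosome sampling from the non-ASB pool
        bg: list[SnpRecord] = []
        if pool:
            by_chrom: dict[str, list[SnpRecord]] = {}
            for s in pool:
                by_chrom.setdefault(s.coord_hap1.chromosome, []).append(s)
            for chrom in sorted(by_chrom):
                sub = by_chrom[chrom]
                take = max(1, round(n_bg * len(sub) / len(pool)))
                take = min(take, len(sub))
                idx = rng.choice(len(sub), size=take, replace=False)
                bg.extend(sub[i] for i in sorted(idx))
        flags = input_bias_filter(
            [c.snp for c in calls], list(snps), bg,
            half_window=cfg.input_half_window,
            alpha_percentile=cfg.input_percentile,
            min_background=cfg.min_background_obs)
        by_id = {f["snp_id"]: f for f in flags}
        for c in calls:
            f = by_id[c.snp.id]
            c.input_bias_stat = f["input_bias_stat"]
            c.passed_input_filter = f["passed_input_filter"]
            c.input_flag = f["input_flag"]
    report["n_final"] = sum(1 for c in calls if c.passed_input_filter)
    return AsbResult(calls=calls, p_null=p_null, report=report)
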