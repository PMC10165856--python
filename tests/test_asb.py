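import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import haschseq as hs
from haschseq.asb import (
    AsbConfig,
    binomial_bias_test,
    binomial_bias_test_many,
    bonferroni_adjust,
    build_linkage_groups,
    call_asbs,
    coverage_filter,
    estimate_null_frequency,
    input_bias_filter,
    restrict_to_peaks,
    select_lead_snp,
)
from conftest import make_snp


def brute_force_minlike_p(k: int, n: int, p: float) -> float:
    """Independent oracle: direct pmf enumeration with math.comb."""
    q = 1.0 - p
    pmf = [math.comb(n, j) * p**j * q**(n - j) for j in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(x for x in pmf if x <= obs * (1 + 1e-7)))


# ---------------------------------------------------------------------------
# coverage filter and null frequency
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ip1,ip2,kept", [
    (1, 25, True),      # boundary satisfies both conditions
    (0, 100, False),    # violates the per-allele minimum
    (12, 12, False),    # violates the max-allele minimum
    (25, 1, True),
])
def test_coverage_filter_boundaries(ip1, ip2, kept):
    snp = make_snp(ip1=ip1, ip2=ip2)
    assert (len(coverage_filter([snp])) == 1) is kept


def test_coverage_filter_drops_scaffolds():
    snps = [make_snp(sid="a", chrom="chr1"), make_snp(sid="b", chrom="scaffold_93")]
    out = coverage_filter(snps, declared_chromosomes={"chr1"})
    assert [s.id for s in out] == ["a"]


def test_null_frequency_median():
    snps = [make_snp(sid=f"s{i}", ip1=k, ip2=100 - k) for i, k in enumerate((40, 50, 60))]
    assert estimate_null_frequency(snps) == pytest.approx(0.5)
    same = [make_snp(sid=f"t{i}", ip1=494, ip2=506) for i in range(3)]
    assert estimate_null_frequency(same) == pytest.approx(0.494)
    with pytest.raises(hs.StatisticsError):
        estimate_null_frequency([])


def test_null_frequency_matches_sort_oracle(rng):
    ks = rng.binomial(1000, 0.48, size=10_001)
    snps = [make_snp(sid=f"s{i}", ip1=int(k), ip2=int(1000 - k)) for i, k in enumerate(ks)]
    freqs = sorted(k / 1000 for k in ks)
    assert estimate_null_frequency(snps) == pytest.approx(freqs[5000])
    assert abs(estimate_null_frequency(snps) - 0.48) < 0.01


# ---------------------------------------------------------------------------
# binomial test
# ---------------------------------------------------------------------------

def test_binomial_test_worked_examples():
    assert binomial_bias_test(10, 20, 0.5) == pytest.approx(1.0)
    assert binomial_bias_test(0, 50, 0.5) == pytest.approx(2 * 0.5**50, rel=1e-12)
    expected = brute_force_minlike_p(25, 26, 0.494)
    assert binomial_bias_test(25, 26, 0.494) == pytest.approx(expected, rel=1e-12)


def test_binomial_test_invalid_arguments():
    with pytest.raises(hs.InputError):
        binomial_bias_test(5, 4, 0.5)
    with pytest.raises(hs.InputError):
        binomial_bias_test(-1, 4, 0.5)
    with pytest.raises(hs.InputError):
        binomial_bias_test(1, 4, 1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(n=st.integers(1, 150), kf=st.floats(0, 1), p=st.sampled_from([0.3, 0.494, 0.5, 0.7]))
def test_binomial_test_matches_scipy_binomtest(n, kf, p):
    """scipy's exact two-sided binomial test is the independent cross-check."""
    k = int(round(kf * n))
    ours = binomial_bias_test(k, n, p)
    ref = stats.binomtest(k, n, p, alternative="two-sided").pvalue
    assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)


def test_vectorised_binomial_equals_scalar(rng):
    ns = rng.integers(1, 120, size=300)
    ks = np.array([rng.integers(0, n + 1) for n in ns])
    many = binomial_bias_test_many(ks, ns, 0.494)
    for k, n, p in zip(ks, ns, many):
        assert p == pytest.approx(binomial_bias_test(int(k), int(n), 0.494), rel=1e-12)


def test_bonferroni_examples_and_rank_preservation(rng):
    assert bonferroni_adjust([1e-9], 429_236)[0] == pytest.approx(4.29236e-4)
    assert bonferroni_adjust([0.5], 1000)[0] == 1.0
    ps = rng.random(100)
    adj = bonferroni_adjust(ps, 150)
    order = np.argsort(ps, kind="stable")
    assert np.all(np.diff(adj[order]) >= 0)     # weakly order-preserving
    with pytest.raises(hs.InputError):
        bonferroni_adjust([0.1, 0.2], 1)


# ---------------------------------------------------------------------------
# peaks, linkage, leads
# ---------------------------------------------------------------------------

def test_restrict_to_peaks_half_open_boundary():
    peak = hs.Peak("p", "chr1", 100, 200, 150)
    inside = make_snp(sid="in", pos=150)
    edge = make_snp(sid="edge", pos=200)
    start = make_snp(sid="start", pos=100)
    got = restrict_to_peaks([inside, edge, start], [peak])
    assert {s.id for s, _ in got} == {"in", "start"}


def test_restrict_to_peaks_matches_quadratic_oracle(rng):
    peaks = []
    for i in range(50):
        s = int(rng.integers(0, 100_000))
        e = s + int(rng.integers(50, 500))
        peaks.append(hs.Peak(f"p{i}", "chr1", s, e, (s + e) // 2))
    snps = [make_snp(sid=f"s{i}", pos=int(rng.integers(0, 100_500))) for i in range(1000)]
    got = {s.id for s, _ in restrict_to_peaks(snps, peaks)}
    expected = {s.id for s in snps
                if any(p.start <= s.coord_hap1.position < p.end for p in peaks)}
    assert got == expected


def test_overlapping_peaks_assign_nearest_summit():
    p1 = hs.Peak("p1", "chr1", 0, 300, 50)
    p2 = hs.Peak("p2", "chr1", 100, 400, 260)
    snp = make_snp(pos=250)
    (_, pid), = restrict_to_peaks([snp], [p1, p2])
    assert pid == "p2"


def test_linkage_group_examples():
    groups = build_linkage_groups([100, 200, 400], window=150)
    assert [sorted(g) for g in groups] == [[0, 1], [2]]
    groups = build_linkage_groups([0, 140, 280], window=150)
    assert len(groups) == 1 and sorted(groups[0]) == [0, 1, 2]
    assert build_linkage_groups([], window=150) == []


def _union_find_partition(positions, window):
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    out = {}
    for i in range(len(positions)):
        out.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in out.values()}


def test_linkage_groups_match_union_find_oracle(rng):
    positions = sorted(int(x) for x in rng.integers(0, 20_000, size=500))
    got = {frozenset(g) for g in build_linkage_groups(positions, window=150)}
    assert got == _union_find_partition(positions, 150)


def test_lead_snp_selection_and_ties(rng):
    assert select_lead_snp([(180, "a"), (220, "b")], summit=190) == "a"
    assert select_lead_snp([(185, "a"), (195, "b")], summit=190) == "a"  # tie -> smaller pos
    for _ in range(200):
        members = [(int(rng.integers(0, 1000)), f"s{i}") for i in range(int(rng.integers(1, 8)))]
        summit = int(rng.integers(0, 1000))
        best = min(members, key=lambda m: (abs(m[0] - summit), m[0], m[1]))[1]
        assert select_lead_snp(members, summit) == best


# ---------------------------------------------------------------------------
# input-bias filter
# ---------------------------------------------------------------------------

def _snp_grid(rng, n, depth=60, frac=0.5, chrom="chr1", start=0, spacing=100, prefix="bg"):
    out = []
    for i in range(n):
        k = int(rng.binomial(depth, frac))
        out.append(make_snp(sid=f"{prefix}{i}", chrom=chrom, pos=start + i * spacing,
                            in1=k, in2=depth - k))
    return out


def test_input_filter_percentile_and_degenerate_rules(rng):
    bg = _snp_grid(rng, 300, frac=0.5)
    artifact = make_snp(sid="bad", chrom="chr1", pos=200_000, in1=57, in2=3)
    clean = make_snp(sid="ok", chrom="chr1", pos=300_000, in1=30, in2=30)
    nocov = make_snp(sid="nocov", chrom="chr2", pos=100, in1=0, in2=0)
    allsnps = bg + [artifact, clean, nocov]
    flags = {f["snp_id"]: f for f in input_bias_filter(
        [artifact, clean, nocov], allsnps, bg)}
    assert not flags["bad"]["passed_input_filter"]
    assert flags["ok"]["passed_input_filter"]
    assert flags["nocov"]["passed_input_filter"]
    assert flags["nocov"]["input_flag"] == "no-input-coverage"

    # empirical percentile threshold agrees with a sort-based oracle
    null_stats = np.array([s.input_count_hap1 / (s.input_count_hap1 + s.input_count_hap2)
                           for s in bg])
    lo, hi = np.percentile(null_stats, [5, 95])
    assert artifact.input_count_hap1 / 60 > hi


def test_input_filter_requires_enough_background(rng):
    bg = _snp_grid(rng, 10)
    with pytest.raises(hs.StatisticsError):
        input_bias_filter([make_snp()], bg, bg, min_background=50)


# ---------------------------------------------------------------------------
# the full funnel
# ---------------------------------------------------------------------------

def test_call_asbs_empty_peaks_yields_no_calls(bundle):
    res = call_asbs(bundle.snps, [], AsbConfig())
    assert res.calls == []


def test_funnel_is_monotone(pipeline_result):
    r = pipeline_result.asb.report
    assert (r["n_input_snps"] >= r["n_covered"] >= r["n_significant"]
            >= r["n_in_peaks"] >= r["n_linkage_groups"] >= r["n_leads"]
            >= r["n_final"])


def test_calling_is_haplotype_symmetric(bundle):
    """Swapping haplotype labels flips every call's direction, same ASB set."""
    def swap(s):
        return hs.SnpRecord(
            id=s.id, coord_hap1=s.coord_hap2, coord_hap2=s.coord_hap1,
            allele_hap1=s.allele_hap2, allele_hap2=s.allele_hap1,
            ip_count_hap1=s.ip_count_hap2, ip_count_hap2=s.ip_count_hap1,
            input_count_hap1=s.input_count_hap2, input_count_hap2=s.input_count_hap1,
            flank_hap1=s.flank_hap2, flank_hap2=s.flank_hap1)

    cfg = AsbConfig(apply_input_filter=False)
    res = call_asbs(bundle.snps, bundle.peaks, cfg)
    swapped = call_asbs([swap(s) for s in bundle.snps], bundle.peaks, cfg)
    assert {c.snp.id for c in res.calls} == {c.snp.id for c in swapped.calls}
    dir_a = {c.snp.id: c.direction for c in res.calls}
    dir_b = {c.snp.id: c.direction for c in swapped.calls}
    flip = {"hap1": "hap2", "hap2": "hap1"}
    assert all(dir_b[i] == flip[d] for i, d in dir_a.items())
    assert swapped.p_null == pytest.approx(1.0 - res.p_null)
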