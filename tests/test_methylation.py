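import numpy as np
import pandas as pd
import pytest

import haschseq as hs
from haschseq.methylation import (
    classify_differential,
    hypo_binding_concordance,
    inbred_f1_concordance,
    methylation_at_asbs,
    methylation_metaprofile,
)
from haschseq.models import MethylationTrack


def make_track(rows, hap="hap1", context="CG"):
    df = pd.DataFrame(rows, columns=["chromosome", "position", "methylated", "total"])
    return MethylationTrack(hap, context, df)


@pytest.mark.parametrize("l1,l2,diff,hypo", [
    (0.05, 0.80, True, "hap1"),
    (0.80, 0.05, True, "hap2"),
    (0.05, 0.50, False, "none"),
    (0.70, 0.10, True, "hap2"),      # rule boundaries are inclusive
    (0.69, 0.10, False, "none"),
    (None, 0.90, False, "none"),     # undefined level -> never differential
])
def test_differential_rule(l1, l2, diff, hypo):
    assert classify_differential(l1, l2) == (diff, hypo)


def test_differential_rule_is_haplotype_symmetric(rng):
    for _ in range(200):
        l1, l2 = rng.random(), rng.random()
        d, h = classify_differential(l1, l2)
        d2, h2 = classify_differential(l2, l1)
        assert d == d2
        assert {None: None, "none": "none", "hap1": "hap2", "hap2": "hap1"}[h] == h2


def test_pooled_levels_match_brute_force(rng):
    """Window levels equal direct per-cytosine read sums on 500 loci."""
    rows = []
    for pos in range(0, 50_000, 7):
        t = int(rng.integers(0, 30))
        m = int(rng.integers(0, t + 1)) if t else 0
        rows.append(("chr1", pos, m, t))
    track1 = make_track(rows, "hap1")
    track2 = make_track(rows, "hap2")
    df = pd.DataFrame(rows, columns=["chromosome", "position", "methylated", "total"])
    loci = [(f"s{i}", "chr1", int(p), "chr1", int(p))
            for i, p in enumerate(rng.integers(100, 49_000, size=500))]
    out = methylation_at_asbs(loci, track1, track2, half_window=20)
    for (sid, _, p, _, _), m in zip(loci, out):
        win = df[(df.position >= p - 20) & (df.position <= p + 20)]
        tot = win.total.sum()
        expected = None if tot == 0 else win.methylated.sum() / tot
        if expected is None:
            assert m.level_hap1 is None
        else:
            assert m.level_hap1 == pytest.approx(expected, abs=1e-12)
            assert m.level_hap2 == pytest.approx(expected, abs=1e-12)


def test_split_records_at_same_position_are_pooled():
    a = make_track([("chr1", 100, 6, 10)])
    b = make_track([("chr1", 100, 2, 4), ("chr1", 100, 4, 6)])
    assert a.window_counts("chr1", 90, 110) == b.window_counts("chr1", 90, 110) == (6, 10)


def test_per_cytosine_mode_differs_from_pooled():
    track = make_track([("chr1", 100, 0, 100), ("chr1", 110, 9, 10)])
    loci = [("s", "chr1", 105, "chr1", 105)]
    pooled = methylation_at_asbs(loci, track, track, mode="pooled")[0]
    percyt = methylation_at_asbs(loci, track, track, mode="per_cytosine")[0]
    assert pooled.level_hap1 == pytest.approx(9 / 110)
    assert percyt.level_hap1 == pytest.approx((0.0 + 0.9) / 2)


def test_metaprofile_flat_at_uniform_half():
    rows = [("chr1", p, 5, 10) for p in range(8_000, 12_001, 10)]
    t1, t2 = make_track(rows, "hap1"), make_track(rows, "hap2")
    prof = methylation_metaprofile([("s", "chr1", 10_000, "chr1", 10_000, 95.0)], t1, t2)
    vals = prof["hap1_high"].dropna()
    assert len(vals) > 300
    assert np.allclose(vals, 0.5)
    assert prof["hap1_low"].isna().all()        # no low-affinity hap1 stratum


def test_metaprofile_direction_on_planted_data(bundle, pipeline_result):
    """Hypermethylated low-affinity alleles raise the low-affinity centre bins."""
    calls = pipeline_result.asb.calls
    loci = [(c.snp.id, c.snp.coord_hap1.chromosome, c.snp.coord_hap1.position,
             c.snp.coord_hap2.chromosome, c.snp.coord_hap2.position, c.bias_pct_hap1)
            for c in calls]
    prof = methylation_metaprofile(loci, bundle.methylation[("hap1", "CG")],
                                   bundle.methylation[("hap2", "CG")])
    center = (prof["bin_start_offset"] >= -20) & (prof["bin_start_offset"] < 20)
    low = np.nanmean(np.concatenate([prof.loc[center, "hap1_low"].to_numpy(),
                                     prof.loc[center, "hap2_low"].to_numpy()]))
    high = np.nanmean(np.concatenate([prof.loc[center, "hap1_high"].to_numpy(),
                                      prof.loc[center, "hap2_high"].to_numpy()]))
    assert low > high


def test_metaprofile_stratification_counts_match_filter_oracle(pipeline_result, bundle):
    calls = pipeline_result.asb.calls
    loci = [(c.snp.id, c.snp.coord_hap1.chromosome, c.snp.coord_hap1.position,
             c.snp.coord_hap2.chromosome, c.snp.coord_hap2.position, c.bias_pct_hap1)
            for c in calls]
    prof = methylation_metaprofile(loci, bundle.methylation[("hap1", "CG")],
                                   bundle.methylation[("hap2", "CG")])
    n_high = sum(1 for c in calls if c.bias_pct_hap1 >= 85)
    n_low = sum(1 for c in calls if c.bias_pct_hap1 <= 15)
    assert prof.attrs["n_loci"]["hap1_high"] == n_high
    assert prof.attrs["n_loci"]["hap2_high"] == n_low


def test_concordance_examples_and_planted_correlation(rng):
    diffs = [(f"s{i}", float(x)) for i, x in enumerate(rng.normal(0, 0.4, size=1000))]
    assert inbred_f1_concordance(diffs, diffs)["r"] == pytest.approx(1.0)
    neg = [(s, -v) for s, v in diffs]
    assert inbred_f1_concordance(diffs, neg)["r"] == pytest.approx(-1.0)

    r_target = 0.95
    x = rng.normal(0, 1, size=1000)
    y = r_target * x + np.sqrt(1 - r_target**2) * rng.normal(0, 1, size=1000)
    got = inbred_f1_concordance([(f"s{i}", v) for i, v in enumerate(x)],
                                [(f"s{i}", v) for i, v in enumerate(y)])
    assert got["r"] == pytest.approx(r_target, abs=0.02)

    with pytest.raises(hs.StatisticsError):
        inbred_f1_concordance(diffs[:2], diffs[:2])


def test_hypo_binding_concordance_on_planted_data(bundle, pipeline_result):
    """Methylation-driven loci bind the hypomethylated allele by construction."""
    calls = pipeline_result.asb.calls
    meth = pipeline_result.methylation_calls["CG"]
    directions = {c.snp.id: c.direction for c in calls}
    res = hypo_binding_concordance(meth, directions)
    truth = bundle.truth
    planted = set(truth.loc[truth.cause == "methylation", "snp_id"])
    assert res["n_differential"] >= 0.8 * len(planted & set(directions))
    assert res["fraction"] > 0.9
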