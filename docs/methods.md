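# Methods

This note documents the statistical model, the default parameters, the
numerical choices, and what the synthetic-data generator does and does
not emulate.

## Allelic-imbalance model

At a heterozygous SNP covered by $n$ IP reads, the haplotype-1 count is
modelled as $k \sim \mathrm{Bin}(n, p_0)$ under the null of equal
binding. $p_0$ defaults to the **median** observed allele frequency over
covered SNPs rather than 0.5: a global offset of the median from 0.5
reflects residual mapping asymmetry between the two haplotype
assemblies, which would otherwise inflate calls genome-wide. A fixed
$p_0$ (e.g. 0.5) can be set in `AsbConfig`.

The two-sided p-value uses the minimum-likelihood definition — the sum
of $\mathrm{Bin}(n, p_0)$ probabilities over all outcomes no more likely
than the observed one — not tail doubling. With $p_0 \ne 0.5$ the
distribution is asymmetric and tail doubling can exceed 1 or misweight
the short tail. Probability-mass ties are resolved with a relative
tolerance of $1 + 10^{-7}$ (the convention of R's `binom.test` and
scipy's `binomtest`, which serve as independent cross-checks in the test
suite). The implementation enumerates the pmf directly; the family size
for Bonferroni correction is the number of SNPs passing the coverage
filter, i.e. the tested family.

### Funnel parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_each` | 1 | reads | both alleles observed at all |
| `min_one` | 25 | reads | enough depth for a meaningful frequency |
| `alpha` | 0.001 | adjusted p | stringent genome-wide calling |
| `linkage_window` | 150 | bp | ~insert size; linked SNPs are co-significant |
| `input_half_window` | 1000 | bp | pooling window for the input statistic |
| `input_percentile` | 5 | % | two-tail empirical exclusion |

**Linkage grouping** is transitive single-linkage chaining: SNPs join a
group when a chain of consecutive member pairs each ≤ 150 bp apart
connects them. A "rolling window" could also be read as fixed
non-overlapping windows; chaining was chosen because it is
order-independent and has no phase artifacts at window borders. Lead-SNP
ties (equal distance to summit) break to the smaller position, then
lexicographic id, making calls fully deterministic.

**Input-bias statistic**: the count-weighted pooled fraction
$\sum k_i^{\mathrm{input}} / \sum n_i^{\mathrm{input}}$ over all SNPs
within ±1 kb, not the mean of per-SNP fractions — low-coverage SNPs
would otherwise dominate the variance. Candidates with zero input reads
in the window **pass** with flag `no-input-coverage`: the filter is an
exclusion test, and absence of evidence is not evidence of bias. The
empirical null is the same statistic at background SNPs sampled
proportionally per chromosome from the covered non-ASB pool; fewer than
`min_background_obs` (50) defined null observations is an error, since
the percentiles would be meaningless. Calls are returned with
`passed_input_filter` set rather than removed, so downstream consumers
can choose the detection set or the stricter final set.

When one SNP lies in several overlapping peaks it is assigned to the
peak with the nearest summit — the lead-SNP rule needs a unique summit.

## Feature annotation

Eight mutually exclusive classes: exon, intron, 5′UTR, 3′UTR, 1 kb
upstream–TSS, TTS–1 kb downstream, 5–1 kb upstream, intergenic.
Priority across genes: exon > intron > UTR > 1 kb upstream > 1 kb
downstream > 1–5 kb upstream; ties at equal priority break to the
nearest TSS. Within one gene, annotated UTR intervals take precedence
over the exon class (UTRs are exon sub-intervals); when a gene
annotation lacks UTRs, that sequence space falls to exon/upstream
classes. Upstream/downstream windows are strand-oriented, for minus-strand genes
too. Target genes of a variant are all genes
with the variant within [TSS − 5 kb, TTS + 1 kb] strand-oriented; the
promoter flag used for expression linkage is a 3-kb window upstream of
the TSS.

## Motif analysis

Motifs are IUPAC strings; reverse complements are always added
(the BRRE pair is mutually reverse-complementary, the G-box is
palindromic, so this is a no-op for the canonical sets but matters for
user-supplied sets). A motif call requires the match window to contain
the central SNP base — a match elsewhere cannot be altered by the SNP.
Fragments of unequal allele length (indels) are uninformative and
flagged. The positional profile reports raw motif-start counts per
offset on the high-affinity allele; a weighted central-enrichment
statistic (as in CentriMo-style tools) is intentionally not reimplemented.

## Methylation analysis

Levels are pooled-read weighted over cytosines of one context within
±20 bp on each haplotype's own coordinate system (tracks are mapped
per-genome, so homologous windows may be indel-shifted). A
per-cytosine-fraction mean is available (`mode="per_cytosine"`); pooled
is the default because it is robust at low per-cytosine coverage.
At least one covered cytosine (configurable) is required for a defined
level; undefined levels never classify as differential and are excluded
from correlations. The differential rule — one allele ≥ 70%, the other
≤ 10% — is symmetric in haplotype labels. Metaprofiles stratify ASBs at
≥ 85% / ≤ 15% binding bias and average methylation per 10-bp bin up to
±2 kb, coverage-weighted; empty bins are missing, not zero.

## Enrichment

The hypergeometric urn pools query and background variants (hits as
successes) and asks for the upper tail of the query hit count — the urn
construction is declared here because several conventions exist; a
one-sided Fisher test is available as an option and agrees in tail
direction. GWAS hits are treated as points (intervals allowed); the hit
window is 2 kb for GWAS and containment (window 0) for enhancer
intervals, with ±10 kb density profiles available separately. Per-trait
results carry unadjusted p-values plus a Benjamini–Hochberg column.

## ASE linkage

Filters: ≥ 20 pooled reads, ≥ 1 read per allele; allele-biased at
≥ 1.5-fold in either direction. With replicate columns the fold change
is averaged over replicates where both alleles are covered; filters
always apply to pooled counts. The ASB–ASE association is a two-sided
Fisher exact test on the 2×2 table of (promoter-ASB vs other genes) ×
(biased vs not); an optional binomial test per gene is available but the
fold rule alone is the default, since the published filter set is the
fold rule. Binding-vs-expression direction is reported as a
cross-tabulation only — no causal claim.

## Synthetic data generator

Defaults (the standard conditions of the test suite): 2 chromosomes ×
1 Mb; 120 non-overlapping peaks of 200–600 bp; 50 true ASBs placed
within ±10 bp of a summit, each in its own peak; 500 null SNPs (70%
inside peaks); IP/input depth fixed at 60 reads; null allele frequency
0.494; true-ASB bias 0.9 drawn beta-binomially with ρ = 0.01
(replicate-level overdispersion); 40% of true ASBs motif-driven (a
canonical BRRE/G-box planted on the high-binding allele, destroyed by
the SNP on the other; all other loci are rejection-sampled to carry no
canonical motif over the SNP), 30% methylation-driven (CG level 0.85 on
the low-binding allele vs 0.03, within ±20 bp, decaying outward); 2% of
null SNPs sit in regional input artifacts where every SNP of the peak
shares a 0.95 input and IP bias — mapping/assembly artifacts bias whole
segments, and a single-SNP artifact would be diluted away by balanced
neighbours in the ±1 kb pooled window. GWAS hits land within ±1.9 kb of
30% of true ASBs under one designated trait; enhancers of 1 kb cover 30%
of true ASBs; 60% of promoter-ASB genes have expression coupled to the
binding bias, with activating and repressing sign mixed 50/50 so binding
and expression direction are near-independent, as in real regulons.

Read depth is fixed rather than jittered by default: the binomial test
conditions on the observed total, so depth variance is orthogonal to the
method; `depth_jitter=True` enables Poisson totals. Sequences are i.i.d.
uniform with motifs planted explicitly — no genome composition, no LD
structure, no read-level simulation, no indels beyond fragment-shift
flags. Consequently, passing tests demonstrate the correctness of the
statistics and the bookkeeping (coordinates, strands, windows,
determinism), not robustness to alignment artifacts, GC bias, or
reference bias beyond a global allele-frequency offset; those effects
enter real analyses upstream of this package's inputs.

All randomness flows from one seed through a named `SeedSequence`
hierarchy (peaks, SNPs, counts, flanks, methylation, GWAS, genes,
expression), so identical seeds give byte-identical bundles and modules
can be regenerated independently.

## Problem sizes used by the test and acceptance runs

Worked-example statistics are computed directly from published per-group
counts (e.g. 213/2730 vs 125/136,500; 199/374 vs 3207/7231). Simulation
checks use the default bundle above; the null-calibration check uses
10,000 all-null SNPs; exact-oracle equivalence covers all binomial
configurations with n ≤ 200 over a null-frequency grid and
hypergeometric urns up to 60. These sizes keep the full suite within a
few minutes on one core while leaving every statistical property
testable at meaningful precision.

## Known limitations

* Read counting, peak calling, whole-genome alignment, methylation
  calling and differential-expression modelling are consumed as inputs,
  never recomputed.
* The input-bias filter is purely empirical (percentiles of a matched
  null); no parametric input test is offered.
* Minor-allele frequencies for background matching are input columns;
  no population-genetic computation is performed.
* Gene annotation is gene-level; transcript isoforms are not modelled.
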