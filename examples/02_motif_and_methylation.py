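"""Classify the putative causes of allele-specific binding.

For each called ASB, compare the 11-bp allelic fragments around the SNP
for canonical motif alterations (BRRE, G-box), and the +/-20 bp
haplotype methylation levels for differential CG methylation.
"""

import haschseq as hs

bundle = hs.simulate_dataset(seed=1)
result = hs.run_pipeline(bundle, seed=1)

print("motif alterations (canonical motif on the high-affinity allele):")
for name, summary in result.motif_summary.items():
    if summary["n_informative"]:
        print(f"  {name}: {summary['n_canonical_on_high']}/{summary['n_informative']} "
              f"canonical-on-high (p vs 50%: {summary['p_value']:.2e})")

meth = result.methylation_calls["CG"]
n_diff = sum(m.differential for m in meth)
print(f"differential CG methylation (one allele >=70%, other <=10%): "
      f"{n_diff}/{len(meth)} ASBs")

directions = {c.snp.id: c.direction for c in result.asb.calls}
conc = hs.hypo_binding_concordance(meth, directions)
print(f"binding biased toward the hypomethylated allele at "
      f"{conc['n_concordant']}/{conc['n_differential']} differential loci")

# A fraction near 1.0 means methylation is on the low-binding allele, the
# expected direction if CG methylation represses TF binding.
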