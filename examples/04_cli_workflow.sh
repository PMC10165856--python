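#!/bin/sh
# The same analysis as a shell workflow: simulate a bundle, call ASBs,
# annotate them, sample matched background, and test GWAS enrichment.
set -e

haschseq simulate --seed 1 --out-dir sim/
haschseq call-asb --snps sim/snps.tsv --peaks sim/peaks.bed \
    --seed 1 --out asb.tsv --report report.json
haschseq annotate --variants asb.tsv --genes sim/genes.gff3 --out annotated.tsv
haschseq sample-bg --snps sim/snps.tsv --asb asb.tsv --genes sim/genes.gff3 \
    --multiplier 50 --seed 17 --out bg.tsv
haschseq enrich --asb asb.tsv --bg bg.tsv --features sim/gwas.tsv \
    --group-col trait --window 2000 --out gwas_enrichment.tsv
haschseq ase --counts sim/expression.tsv --asb-genes annotated.tsv --out ase.tsv

# or, all stages at once with a single seed:
haschseq run-all --seed 1 --out-dir run/
cat run/report.json
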