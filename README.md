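# nsrscan

Toolkit for comparing the two haplotypes of a phased diploid genome
assembly. It detects collinear gene blocks from protein hits and gene order
(MCScanX-style parameters), estimates NG86 Ka/Ks on codon alignments,
classifies gene pairs as homologous, calls **non-syntenic regions (nSRs)**
with a sliding-window scan, annotates tandem gene duplications (TDG/SSTDG),
runs exact hypergeometric enrichment/depletion with Benjamini–Hochberg
correction, contrasts expression correlation between regions, and assigns
Ref/Alt haplotype labels from telomere arrays and assembly gaps.

It also ships a forward **simulator** of transposon-mediated unequal
crossing over (NAHR) that produces a diverging haplotype pair with tandem
gene expansions, repeat-rich disordered tracts, and full ground truth — so
the entire pipeline is testable without any external data.

## Quick start

```bash
# generate a synthetic haplotype pair with 40 NAHR events and ground truth
nsrscan simulate --seed 42 --outdir data/ --genes-per-scaffold 1000 \
    --n-nahr-events 40

# run everything: QC, Ref/Alt, collinearity, Ka/Ks, nSR windows,
# TE enrichment, expression correlation
nsrscan run-all --data-dir data/ --out-dir out/

# or individual stages
nsrscan telomeres --fasta data/hap1.genome.fasta --out out/telomeres.bed
nsrscan call-nsr --data-dir data/ --out-dir out/ --window 500000 \
    --step 100000 --min-genes 15 --max-homolog-frac 0.15
nsrscan enrich --table items.tsv --out enrichment.tsv --tail upper
```

A dataset directory holds, per haplotype, `<hap>.genes.gff3`,
`<hap>.genome.fasta`, `<hap>.cds.fasta` and optionally
`<hap>.expression.tsv` / `<hap>.repeats.out`, plus a shared 12-column
`hits.tsv` (BLAST outfmt-6 style). `nsrscan simulate` emits exactly this
layout together with `truth_nsr.bed` and `events.tsv`.

Native MCScanX output can be substituted for the built-in chaining with
`--import-collinearity blocks.collinearity`.

### Defaults

All thresholds default to the published procedure: chaining with
match_score 50, match_size 10, gap_penalty −1, overlap_window 5,
e-value cut 1e−5, max gaps 25; homologous = Ks < 0.3 (metric selectable
among ks/ka/ka_over_ks); windows of 500 kb at 100 kb step, non-syntenic
when a window has ≥ 15 genes of which < 15% are homologous. Reported
percentages are truncated (not rounded) to one decimal, matching the
source convention.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes brute-force oracles (pathway-enumeration NG86, exact
hypergeometric enumeration, exhaustive chain search, quadratic TDG scan)
and seeded parameter-recovery runs in which the nSR caller must re-find
simulated disordered tracts with Jaccard ≥ 0.7.

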