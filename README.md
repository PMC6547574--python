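# ssrseq

High-throughput SSR (simple sequence repeat / microsatellite) genotyping
from amplicon sequencing reads, for genetic-background screening of crop
lines — e.g. checking how much of a recipient genome survives
marker-assisted backcrossing, transgenesis or genome editing in inbred
rice.

Electrophoresis-based SSR detection only resolves length differences
(reliably only > 5 bp) and scales poorly past a few dozen markers.
Sequencing the amplicons instead reads out each repeat tract directly:
a locus's genotype is written as the motif followed by the repeat
count (`AT10`; two tracts separated by fewer than 10 bp are genotyped
jointly, e.g. `AAT4_AAT10`), so same-length alleles with different base
composition are still distinguishable and hundreds of loci can be typed
per run.

## Method

For each locus, reads that span the repeat tract are identified by
anchoring on the flanking sequences (12 bp anchors, ≤ 1 mismatch, both
strands searched), and the number of complete in-register motif copies
between the anchors is counted. Per locus:

- the allele with the most supporting reads is the **major allele**
  (genotype; the material is assumed inbred and homozygous), and its
  read count is the **coverage**;
- the **stutter ratio** is *n*(minor allele) / *n*(major allele), a
  direct readout of PCR replication slippage;
- a call is **valid** when coverage ≥ 10 (≥ 20 during panel design) and
  stutter ratio < 0.5.

Panels are designed by a **diversity index**: the number of variety
pairs a locus distinguishes divided by all C(n, 2) pairs (28 for eight
varieties); loci with index > 0.3 lying within 1 Mb of another passing
locus are selected. Two samples are screened by comparing genotypes at
all loci valid in both (**comparable** loci); loci whose genotype
strings differ are **differential**, binned by amplicon-length
difference (0, 1–5, > 5 bp — what electrophoresis cannot / barely / can
see). Differential loci are classified against GFF3 gene models as
CDS / UTR / intron / intergenic, and CDS variants as frameshift-free
when the length change is a multiple of 3.

A stutter-aware simulator (per-read slippage probability, contraction
bias, geometric step size, substitution errors) generates references,
panels and reads with known truth for end-to-end benchmarking.

## Worked example

Simulate 50 loci at 30× depth, genotype the pooled reads, and measure
accuracy against the simulation truth:

```sh
ssrseq simulate --n-loci 50 --depth 30 --seed 7 --out-dir demo
ssrseq genotype --reads demo/reads.fastq --panel demo/panel.tsv \
    --sample S1 --out s1.tsv
ssrseq accuracy --genotypes s1.tsv --truth demo/truth.tsv
```

which logs `50 detected, 49 valid` (one locus drawn with a stutter
ratio above 0.5 is filtered) and prints

```json
{
  "accuracy": 1.0,
  "n_correct": 49,
  "n_evaluated": 49,
  "n_filtered": 1,
  "n_no_call": 0
}
```

i.e. every locus passing the stutter filter was called to its true
genotype. The genotype table holds one row per locus with the called
genotype, major-allele coverage and stutter ratio:

```text
#sample  amplicon_id  locus_id   genotype  coverage  stutter_ratio  valid
S1       AMPL000000   SSR000000  TGTTA4    19        0.1579         1
S1       AMPL000001   SSR000001  CAAG16    21        0.0952         1
```

Comparing a sample with itself (`ssrseq compare --table-a s1.tsv
--table-b s1.tsv --panel demo/panel.tsv --out cmp.tsv`) reports
`comparable: 49; differential: 0 (0.0%)`, the expected null screen.
`ssrseq select-panel` and `ssrseq annotate` cover panel design and
gene-model annotation; `ssrseq genotype --sam` accepts pre-aligned SAM
instead of FASTQ.

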