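# Methods

## Genotyping model

A simple sequence repeat (SSR) locus is a maximal tandem run of a 1–6 bp
motif; its genotype in one sample is written motif + repeat count
(`AT10`). The material is assumed inbred and effectively homozygous, so
exactly one true allele is expected per locus and the major allele (most
supporting reads) is reported as the genotype. No diploid or
heterozygous calling is attempted.

Reads are assigned to loci and typed without an external aligner:

1. **Assignment.** A 16-mer index over every locus's flanks (both
   strands) maps each pooled read to the unique locus sharing an
   informative flank k-mer. Amplicon reads start at the amplicon ends,
   so the first informative k-mer is normally found within one or two
   probes; k-mers shared between loci are treated as uninformative.
   When reads arrive as SAM, only the stored sequence and the
   reverse-strand flag are consulted (the sequence is restored to
   sequencing strand); coordinates are ignored and typing proceeds
   identically.
2. **Anchoring.** The last `anchor_len` bases of the left flank and the
   first `anchor_len` of the right flank are located in the read (or
   its reverse complement), allowing up to `max_mismatch` substitutions
   each, no indels. A read is used only when each anchor occurs exactly
   once and in order; multiple matches (tandem ambiguity) discard the
   read rather than risk mistyping. Only reads spanning the whole tract
   plus both anchors count — the genotype is a length measurement, so
   there is no partial-evidence rescue.
3. **Counting.** Complete, contiguous, in-register motif copies are
   counted from the tract start; counting stops at the first
   out-of-register base, and the resulting shorter genotype is a
   legitimate allele (interrupted repeats type as their initial perfect
   run). For compound loci the components are counted in order, with
   the known inter-tract gap lengths skipped between them.

Two tracts separated by fewer than 10 bp on one amplicon are merged
into a compound locus and genotyped jointly with an underscore-joined
genotype (`AAT4_AAT10`); a gap of 10 bp or more keeps them independent.
Merging is transitive along chains of close tracts; overlapping tracts
are a panel error.

**Stutter ratio and validity.** PCR slippage produces stutter reads
whose repeat count differs from the template's, typically by whole
motif units. The stutter ratio — second-largest allele count divided by
the largest — summarises how contested a call is: 0 for a single
observed allele, 1 for a tie. A call is valid when coverage (major
allele read count, *not* total depth) is at least `min_coverage` and
the stutter ratio is strictly below `max_stutter`. Defaults:
`min_coverage` 10 for sample screening, 20 during panel design,
`max_stutter` 0.5.

**Tie-breaking.** Equal top counts are resolved toward the allele whose
implied tract length is closest to the panel's reference length, then
lexicographically. Tied calls have stutter ratio 1.0 and can never be
valid under any threshold ≤ 1, so the rule affects determinism only,
never valid output.

**Motifs** are stored exactly as annotated in the panel (forward
strand, annotated phase); no cyclic-rotation canonicalisation is
applied, so genotype strings always match the panel's spelling. No
base-quality trimming is performed by default.

## Panel design

The diversity index of a locus over n varieties is the number of
variety pairs it distinguishes divided by C(n, 2) (28 for n = 8). A
pair is distinguishable only when both varieties have valid calls with
different genotype strings; missing or invalid calls reduce the
numerator while the denominator stays fixed, penalising unreliable
loci. Selection keeps loci with index strictly greater than
`min_diversity` (default 0.3) that lie strictly within `max_gap_bp`
(default 1 Mb) of the nearest other index-passing locus on the same
chromosome; distance is measured between tract starts. The spacing
rule is a deliberate design choice among several defensible readings
of "near other loci": it enforces panel density deterministically, and
a chromosome whose only candidate would otherwise be orphaned keeps
it, so sparse chromosomes are not emptied.

## Sample comparison

A locus valid in both samples is comparable; a comparable locus whose
genotype strings differ is differential. Equality is exact string
equality, so same-length alleles with different base composition are
differential with length-difference bin "0" — precisely the class of
variation electrophoresis cannot see. Compound-vs-simple genotypes at
one locus (e.g. `AAT6` vs `AAT4_AAT10`) compare as ordinary strings and
their lengths as the summed motif × count of each side. Differential
loci are binned by absolute length difference: 0, 1–5, and > 5 bp.
Percentages are reported to one decimal, rounded half-up. Summaries can
be restricted to loci carrying a national-standard marker name, for
comparison against certification-style marker sets.

## Region annotation

Gene models come from GFF3 (gene, mRNA, CDS, five_prime_UTR,
three_prime_UTR, exon; 1-based inclusive). A tract is CDS if it
overlaps any CDS interval by at least one base, else UTR, else intron
when inside a gene span without touching an exon, else intergenic — a
precedence biased toward the functionally strongest call. Strand is
ignored; region identity is strand-independent here. "Non-coding" in
summary terms aggregates intron + intergenic, but the classifier
reports the four base classes so no lossy grouping is baked in. A
differential CDS variant is frameshift-free iff its length difference
is divisible by 3 (any whole-unit change of a trinucleotide motif
therefore is); non-CDS variants are "not applicable". One limitation:
a tract overlapping only the exon of a non-coding transcript (never
CDS or UTR) falls through to intergenic under the literal precedence
rule; with protein-coding models (exon = CDS ∪ UTR) the case cannot
arise.

## Simulator

The simulator emulates targeted amplicon sequencing, not shotgun:
every read covers its whole amplicon, single-end, default read length
300 bp. Each locus gets a random primitive motif (length 1–6, uniform
by default), a repeat count uniform on [4, 20], and 40 bp random flanks
rewritten at the borders so no flank begins or ends with a motif copy
(tracts stay maximal and the constructed count is the truth). A
configurable fraction of amplicons carries two tracts separated by a
1–9 bp motif-free gap to exercise merging.

Stutter is modelled per read: with probability `slippage_prob`
(default 0.12) the tract slips by k whole motif units, k geometric
with parameter `step_q` (default 0.3), contracting with probability
`contraction_prob` (default 0.8, matching the contraction bias of PCR
slippage) and truncated so at least one unit remains. Substitution
errors are then applied at `sub_error` per base (default 0.005); indel
sequencing errors are off by default so tract-length noise is
attributable to the slippage model. Reads are reverse-complemented
with probability 1/2. The slippage defaults were chosen once so that
typical stutter ratios exercise, without saturating, the 0.5 validity
threshold; no instrument-specific stutter distribution is claimed, and
real instrument error profiles (e.g. homopolymer-biased indels) are
not modelled. Passing tests therefore demonstrate correctness of the
calling logic under a plausible slippage regime, not performance on
any particular sequencing chemistry.

All randomness flows from one integer seed through `numpy`'s
`default_rng` (the read generator derives its stream from the same
seed), so FASTA, panel, FASTQ and truth outputs are byte-identical
across runs with the same configuration.

**Accuracy evaluation** divides the number of loci whose called
genotype equals the truth by the number of loci whose call passes a
stated policy; undetected loci (no spanning reads) and policy-filtered
calls are excluded from the denominator and reported separately. The
benchmark in `scripts/acceptance.py` uses 5,000 loci at 10× and 50×
depth and the policy "stutter ratio < 0.5" with no coverage floor —
depth itself is the coverage condition being varied. 5,000 loci keeps
the binomial sampling error of the reported percentage below ~0.1
percentage points while the whole script completes in well under a
minute.

## Numerical and interface choices

- All user-facing coordinates are 1-based inclusive (GFF3 convention);
  no half-open representation is ever serialised.
- Tables are tab-separated text with `#`-prefixed headers and an
  embedded JSON parameter echo (`##` line) rather than spreadsheets,
  for diffability. The echo deliberately excludes timestamps so
  identical runs produce identical bytes.
- Genotype-table validity is always recomputed from the coverage and
  stutter columns on read; the file's own flag is never trusted.
- Row-level parse errors (malformed genotype, negative coverage,
  stutter outside [0, 1]) are collected across the whole file before
  failing, with line numbers.
- Zero spanning reads at a locus is an "undetected" outcome, not an
  error; an empty tally simply produces no call and the locus is
  reported as missing downstream.

## Known limitations

- Flank anchoring assumes the panel's flanks are locus-unique at the
  anchor scale; heavily paralogous loci would need the SAM input path
  with an external aligner's mapping judgement.
- Substitutions inside a tract truncate the counted run (by design);
  at very high substitution rates this inflates short stutter-like
  alleles faster than real slippage would.
- The upstream read-QC of the sequencing provider is not reproduced;
  an optional mean-quality gate exists but is off by default.
- Region classification depends on the gene-model release used;
  classifications against a different annotation release may
  legitimately differ.
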