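# Methods

## Genotype model and the KS-style statistic

The caller treats a locus as a two-point sampling problem. Observations on
one strand are the retained pileup bases (zero-quality bases trimmed), each
weighted by the probability its call is correct, w = 1 − 10^(−Q/10). The
weighted alternate fraction p̂ is compared against the three diploid
genotype expectations (0, ½, 1). The comparison is described in the source
method only as a "Kolmogorov–Smirnov like" distance incorporating base
qualities; on support {ref, alt} the KS sup-distance between the empirical
and expected distributions is exactly |p̂ − p_g|, and that closed form is
adopted as the canonical statistic. The brute-force oracle in the test
suite computes the same quantity independently via the weighted empirical
CDF and exhaustive minimization over genotypes.

Decision rules:

* **standard mode** — per strand, the minimum-distance genotype; combined
  tier `high_quality` requires both strands to agree, both distances within
  `strict_max_distance`, and both depths at least `min_depth_per_strand`.
  A variant genotype therefore always has supporting evidence on both
  strands. Ties in the minimization resolve toward the less variant
  genotype (hom_ref < het < hom_alt).
* **Variant Consensus mode** (lenient tumor mode) — strands are pooled; the
  best of {het, hom_alt} is accepted at tier `lenient` when its distance is
  within `lenient_max_distance` *and* each strand has at least
  `min_alt_obs_per_strand` alternate observations; otherwise the call falls
  back to standard mode. The original tool's description does not say
  whether this mode relaxes the two-strand rule entirely; requiring a
  minimum alternate count per strand is this package's interpretation and
  is configurable.
* **somatic rule** — tumor variant (any tier) over a normal call that is
  `high_quality hom_ref`; anything else is annotated `germline` or
  `ambiguous_normal`.
* The original study compiled calls from two callers; with one caller here,
  the compilation step is emulated by intersecting the standard-mode and
  consensus-mode tumor call sets, keeping the union as the review set.

Default thresholds — strict 0.15, lenient 0.25, min depth/strand 4, min alt
obs/strand 2 — are not stated by the source method; they were fixed once as
reasonable desk-scale values (a strict band half the het spacing, a lenient
band halfway to the next genotype) and are all config-exposed.

Tri-allelic columns evaluate only the highest-weight non-reference base;
the others are carried as notes.

### Numerical choices

Quality weights are quantized to multiples of 2⁻²⁰. Sums of a few thousand
such dyadic values are exact in float64, so weighted fractions are
independent of summation order and the streaming (per-column) and
vectorized (aggregate-array) call paths agree bit-for-bit; the test suite
asserts this equivalence directly. Genotype and alternate-allele ties break
deterministically (less variant genotype; alphabetically first base).

## Pileups and duplicates

Coordinates are 1-based inclusive throughout; BED/bedGraph conversion
happens at the I/O boundary. Zero-quality bases are removed before any
statistic sees them. Reads spanning a deletion contribute no observation at
deleted positions, and deletion-spanning reads are likewise excluded from
depth there (the source method is silent; exclusion is this package's
choice). Overlapping mates are both counted, on their own strands — the
method is silent here too, and independent counting keeps per-strand depths
interpretable. Duplicate marking is a coordinate-key stand-in for Picard:
among reads sharing (contig, pos, strand, mate position) all but the first
are flagged and excluded downstream.

## Somatic indels

Step one removes tumor reads whose template length lies outside (50, 500),
read as an open interval per standard notation, and takes TLEN (outer
fragment span) as the meaning of "insert size". Candidates are one per
distinct left-normalized (contig, start, kind, sequence) with
`min_support` ≥ 2 supporting reads (candidate discovery is re-implemented
from gap operations; the original delegated this to an external toolkit).
Left-normalization shifts an event leftward while the edited haplotype is
unchanged; coordinates in the source are given without a convention, so the
leftmost placement is adopted. Step two counts insertion/deletion
operations in the matched normal intersecting [start − 5, end + 5], both
boundaries inclusive; somatic iff the count is zero. Windows with no normal
coverage are conservatively non-somatic (`no_normal_coverage`).

## Clone-coverage copy number

A clone is the interval from the leftmost to the rightmost mapped base of a
proper pair. The exclusion phrase in the source ("within 2 standard
deviations outside of the insert distance") is contradictory as written; it
is interpreted as excluding pairs outside mean ± 2 SD of the estimated
insert distribution. Fewer than 100 proper pairs refuse estimation
(configurable floor). Windows are non-overlapping 2 kb tiles; a final
partial window is kept when it is at least half a window. The normalization
denominator is the genome-wide mode of integer per-base clone depth over
covered (depth > 0) bases, ties broken toward the smaller depth — the
estimator is not defined in the source, and per-base (rather than
per-window) depth is this package's reading. The per-window statistic is
log₂((tumor_norm + ε)/(normal_norm + ε)) with ε = 0.01, masked where normal
normalized coverage is below 0.1; **positive means tumor gain** (the
source's Methods sentence orders the two samples ambiguously, but its
Results describe amplifications as gains, fixing the direction).
Segmentation is deliberately simple — maximal runs of ≥ `min_windows` (3)
consecutive windows beyond ±0.3 — because no segmentation procedure is
specified; thresholds are config-exposed. A gene is gained/lost when
segments of that call overlap ≥ 50 % of its span.

## Consequence annotation

Gene models are single-transcript CDS exon chains with strand; models whose
CDS length is not a multiple of three are rejected with a warning. Codon
index counts from the CDS start in transcription direction; minus-strand
models reverse-complement both the reference codon and the alternate base.
Translation uses the standard genetic code, written out in full and
cross-checked against Biopython's table in the tests. SNVs are synonymous,
nsSNP, or nonsense; CDS-overlapping indels are frameshift unless their
length is 0 mod 3. External-predictor labels (SIFT/PolyPhen) carried by the
validation fixture are opaque strings and are never recomputed. Splice and
UTR effects are out of scope: anything outside a CDS is `non_coding`.
Transitions are A↔G and C↔T; the Ti/Tv ratio is undefined (None) when no
transversions exist. The validated-mutation fixture is stored at codon
level (gene, codon index, reference/mutated codon) because the original
genomic coordinates refer to an old assembly; consequence tests therefore
run against toy gene models rather than real annotation.

## Timeline classification

Cells are categorical codons (Sanger-trace mixtures are not modelled). A
site's mutant codon is inferred as the unique non-reference codon in its
column. Samples sharing a date are replicates: a mutation is present on a
date if any replicate shows it. A site is `present_at_diagnosis` when the
earliest evaluable date is mutant, `acquired` when the earliest evaluable
date is reference and a later date is mutant, `inconsistent` for
mutant-then-reference reversions, `never_observed` otherwise; N/A cells are
skipped. Classification is invariant to input row order (dates sort it).

## Synthetic data generator

The generator emulates the emulated study's design: uniform-composition
contigs (default 2 + 2 + 1 Mb); germline SNPs at 10⁻³/bp, two-thirds
heterozygous, transition-biased so the Ti/Tv of the call set is near 2.1,
with 87 % of sites entered into a known-sites catalog (both values are the
study's reported germline statistics, used as generator conditions);
somatic SNVs spiked at a configurable VAF (default 0.5 — tumor purity is
not reported in the source, so VAF is exposed directly rather than a
purity × clonality model); 1–7 bp indels (the size range of the five
validated coding indels); CNV segments scaling tumor fragment density by
copy/2; 100 bp paired-end reads from Normal(325, 20) fragments (the
reported 300–350 bp target); default depths 68X tumor / 71X normal (the
reported coverages; tests and the acceptance script use 60X/30X to keep
runs minutes-scale); ~85 % of non-zero base qualities at Q30–Q40 with a low
tail and a configurable zero-quality fraction (echoing the reported 81.3 %
Q30 share); i.i.d. substitution errors at 10⁻³; and PCR duplicates at 5 %
of pairs, sharing both mates' coordinates and alleles.

Reads are emitted pre-aligned at their true coordinates (alignment is out
of scope), with indel carriers encoded through real M/I/D gap operations.
Both mates of a template always agree on its alleles (a deterministic
per-template hash decides somatic carriage). A read overlapping two spiked
indels carries only the first — events are placed ≥ 10 bp apart, and one
gap per read keeps the alignment arithmetic exact. Everything derives from
`numpy.random.default_rng` seeded from the config, so identical seed +
config gives byte-identical outputs.

What the generator does **not** emulate: alignment and mapping error,
soft-clipping, indel-realignment artifacts, GC or mappability bias,
overdispersed coverage, strand bias, FFPE damage, subclonal structure, and
translocations. Passing recovery tests therefore demonstrate correctness of
the calling logic under the stated model, not performance on real tumor
data.

## Problem sizes used by the tests and acceptance script

Unit tests run on a shared 100 kb simulation; the SNV/indel recovery checks
run on the full 5 Mb genome at 60X/30X with 200 spiked somatic SNVs (about
a minute); copy-number recovery uses a 400 kb contig with 60 kb copy-4 and
copy-1 segments; determinism is checked on a 60 kb end-to-end run. The
oracle-equivalence sweep enumerates every pileup of ≤ 12 observations over
four alt/ref quality patterns spanning the Phred range.

## Known limitations

* One gene model per gene; no multi-transcript resolution.
* The somatic caller assumes ploidy 2 and a single alternate allele per
  locus.
* The vectorized engine requires uniform read length (the streaming path
  has no such restriction).
* BAM/CRAM are not read; text SAM suffices at desk scale.
* No GC correction or mappability masking in copy number; no breakpoint or
  translocation detection.
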