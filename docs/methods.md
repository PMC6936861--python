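# Methods

This note documents the models and procedures `apobecsig` implements, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions used at edge cases.

## APOBEC signature enrichment

**Signature definition.** A substitution is APOBEC-signature iff it is C→T
or C→G at a TCW trinucleotide center (W ∈ {A, T}), or the reverse-complement
event G→A or G→C at a WGA center. C→A at TCW is *not* counted: APOBEC
deamination produces uracil, whose replication (U:A pairing) or abasic-site
bypass yields the T and G alternates specifically. Mutations with an N in an
immediate flank, or with no attached context, are uncallable and counted
separately; they enter `n_other`.

**Context windows.** Each mutation carries a window of `flank` bases on each
side of the mutated position (default flank = 20, i.e. a 40 bp surrounding
window; 41 bases including the center). Windows are clipped at chromosome
ends and N-padded to constant length. Two counting conventions are
supported:

* *multiset* (default): each mutation contributes its own window; windows
  of nearby mutations overlap and count multiply. This treats the window as
  an estimate of the local sequence composition available to each mutation.
* *collapsed* (`collapse=True`): the genomic union of the windows is counted
  once. Available because neither convention is obviously superior for very
  dense catalogs; for realistic densities (≤ thousands of mutations per
  genome) the two differ negligibly.

Within the windows, `n_tcw` counts TCA/TCT plus TGA/AGA occurrences (motif
center inside the window) and `n_c` counts C plus G bases. The mutated
position itself is excluded from both counts — the motif destroyed or
created by the mutation should not count as availability — and `n_c`
deliberately includes TCW-center cytosines (the categories are "TCW motifs"
and "C bases", as counted, not a disjoint partition).

**Test and classification.** Per sample, a two-sided Fisher exact test is
applied to [[n_apobec, n_other], [n_tcw, n_c]] (scipy's implementation; the
test suite validates it against exact-rational hypergeometric enumeration).
The reported odds ratio is the sample cross-product ratio
(n_apobec·n_c)/(n_other·n_tcw), with +∞ / 0 conventions when a single
cell zeroes the numerator or denominator and an error when all four cells
are zero. p-values are Benjamini–Hochberg adjusted across the whole cohort
(statsmodels; validated against a hand-written step-up). A sample is
classified APOBEC-mutated iff q < α and OR > θ with strict inequalities;
defaults α = 0.05, θ = 2. Two-sidedness cannot flip a call in practice
because the OR threshold already demands enrichment.

**Minimum estimate.** For classified samples,

    min_estimate = max(0, n_apobec − n_other · n_tcw / n_c),

i.e. the signature count in excess of what a context-blind process
producing the observed non-signature count would yield; clamped above by
n_apobec and defined as exactly 0 for unclassified samples. An alternative
formulation, n_apobec·(1 − 1/OR), is available via
`min_estimate_formula="fraction_of_enrichment"`; the two are algebraically
identical whenever OR is finite, but are kept separate because they degrade
differently at boundary tables. **This estimate is a deliberate lower
bound**: under any background process whose chance of producing
signature-compatible events at TCW is below n_tcw/n_c (true of any
realistic substitution spectrum, since only 4 of the 12 substitution types
are signature-compatible), the subtraction term exceeds the background's
actual signature contribution, so the estimate undershoots the true APOBEC
count — mildly at high APOBEC fractions, substantially as the fraction
approaches zero. The planted-truth tests quantify this: at a planted
fraction of 0.4–0.6 of 2000 mutations the recovered fraction is within 15%
of truth; at 0.2 it is ~30% low.

**Spectra.** 96-channel trinucleotide spectra use the COSMIC channel order
(C>A, C>G, C>T, T>A, T>C, T>G major order; A/C/G/T flank order).
Purine-reference mutations are reverse-complemented into pyrimidine
channels. Channel sums equal the number of callable mutations.

## Unambiguous paralog expression

**Alignment.** The two transcripts are aligned with a global
Needleman–Wunsch in which terminal gap runs in either sequence cost nothing
(free end gaps), via Biopython's `PairwiseAligner`. Default scoring
approximates a high-stringency (~93% similarity) nucleotide matrix:
match +5, mismatch −9.03, gap open −12, gap extend −3 — strong penalties so
only genuinely homologous stretches pair up. Ties between optimal
alignments are broken deterministically by taking the aligner's first
result; the test suite checks optimal *scores* against exhaustive
enumeration for short sequences, which is tie-break independent.

**Unique-region derivation.** Per-column match flags are smoothed with a
centered sliding window (default 51 columns, clamped at alignment ends).
Maximal runs of columns with windowed identity below 0.6 are projected to
each transcript's ungapped 1-based coordinates; runs separated by less than
half a window (chance identity spikes between unrelated segments) are
merged, and regions shorter than 50 nt discarded. With these defaults a
~90%-identical core sits several window-standard-deviations above the
threshold and unrelated segments (~25% chance identity) far below it, so
boundaries land within about half a window of the true homology breakpoint.
Against simulated pairs with planted unique segments (350 nt 5' on one
transcript; 622 and 190 nt segments on the other, mirroring the A3A/A3B
architecture), recovered boundaries are within ±26 nt of truth.

**Read filtering and assignment.** Reads must be primary, mapped, and carry
a CIGAR consisting of one M operation equal to the read length — an
end-to-end, indel-free, unclipped alignment (mismatches remain M, so
sequencing errors do not break the filter). An optional read-length
whitelist (default {75, 101, 105}, the library lengths the procedure was
designed around; `None` accepts any) further restricts counting. A passing
read is assigned to a gene only if its aligned interval is *fully
contained* in a single unique interval; containment is the conservative
reading that guarantees no part of the read touches shared sequence. An
overlap mode exists for sensitivity analyses. In genomic mode regions carry
a chromosome and the read's target must match it.

**Normalization.** Counts are increased by 0.5 (so zero-count samples stay
finite after log10) and divided by either the library's total primary read
count (transcript mode) or the read count of a reference gene such as
*HPRT1* (genomic mode). Estimates are per-gene: they scale with each gene's
unique-region length and are intended for cross-sample comparison; only
length-matched unique regions make cross-gene ratios directly
interpretable (the simulation tests verify 2-fold accuracy and
monotonicity over a 100-fold abundance range in that setting).

## Association analyses

Expression and mutation load are log10-transformed before correlation.
Zero handling is explicit and recorded: `offset1` (log10(x+1), default),
`half_min` (zeros replaced by half the smallest positive value), or `drop`
(zeros removed, with an index map; a sample dropped on either axis is
dropped from both). Correlations are Pearson (two-sided p from the
t transform), with Spearman available but never the default. Group
comparisons use the two-sided Mann–Whitney U test — exact enumeration when
the combined sample size is ≤12 with no ties, tie-corrected normal
approximation otherwise — plus the ratio of group medians as the reported
fold-difference. Subgroups: samples flagged APOBEC-mutated, or samples at
or below the 25th percentile of a gene's expression (linear-interpolation
percentile, ties kept). No multiple-testing correction is applied across
association analyses; raw correlation p-values are reported.

## Synthetic data: what it emulates, and what it does not

**Mutation catalogs.** A reference sequence is drawn iid-uniform and then
motif-seeded until its TCW-site density is within 20% of the target
(default 1/16, the uniform-sequence expectation). A catalog plants
round(f·n) signature events at distinct TCW centers (alternate T vs G split
50/50 by default) and draws the remainder from a background spectrum over
the 12 substitution types (uniform by default) at uniformly chosen
compatible positions. Planted truth is recorded per sample. The generator
emulates the operational APOBEC-vs-background dichotomy the enrichment
statistic targets; it does **not** model full COSMIC signature profiles,
replication-strand or clustering (kataegis) structure, chromatin covariates,
or copy number — so passing tests demonstrate statistical correctness of
the method under its own null, not robustness to every real-genome
confounder.

**Paralog pairs and reads.** A shared core (default 1000 nt) is copied with
point substitutions to the stated identity (default 0.93) and flanked by
independent random unique segments (defaults 350/150 and 622/190 nt).
Reads are emitted directly as alignment records with uniform starts,
full-match CIGARs, and optional uniform substitution errors; per-read truth
records the origin transcript, interval, core overlap, and whether the read
sequence occurs exactly in both transcripts. A FASTQ writer exists for
end-to-end runs through a real aligner, but no aligner is required for the
tests. Not modeled: fragment-length and GC bias, coverage nonuniformity,
spliced alignments, indel errors.

**Cohorts.** Per-gene expression is log-normal (defaults: A3A ln-mean 0,
ln-sd 1; A3B ln-mean 1.5, ln-sd 0.8 — the second paralog more highly
expressed, as in breast panels). A stated fraction of samples (default 0.5,
emulating a 28-sample panel with half APOBEC-mutated) receives a mutation
load round(exp(a + b·ln x + ε)), ε ~ N(0, σ), linked to the first gene's
expression; other samples have a minimum estimate of exactly zero, matching
the estimator's definition. Defaults a = 4, b = 1, σ = 1.33 give a
generating log-scale correlation of 0.60 among flagged samples, the
magnitude reported for real cell-line panels. The mutated flag is assigned
*independently* of expression, so only the flagged subset carries the
expression–load link; cohort-wide correlations additionally depend on how
flags would co-vary with expression in real data, which this generator does
not model.

## Numerical conventions and degenerate inputs

* Catalog loading keeps only single-nucleotide A/C/G/T substitutions;
  indels/MNVs are skipped and counted; exact duplicate records are dropped
  with a warning; loaded + skipped + duplicates reconciles to the input row
  count. Reference-base mismatches during context attachment exclude the
  mutation and are counted.
* Coordinates are 1-based inclusive everywhere except BED input, which is
  converted on read.
* Fisher: all-zero table is an error; single-zero cells follow the ∞/0
  odds-ratio conventions above.
* Minimum estimate with n_c = 0 on a classified sample is an error
  (degenerate context), not a silent zero.
* Pearson requires n ≥ 3 and non-constant vectors; median fold requires a
  positive reference median.
* All generators are bit-reproducible given (config, seed); the CLI records
  parameters, seeds, and input checksums in per-stage JSON manifests, and
  identical configs produce byte-identical TSVs.

## Problem sizes used in the test and acceptance runs

Property checks run at sizes chosen to make their statistical assertions
sharp while keeping the suite quick: 200 null samples of 500 mutations for
the false-classification rate; single 2000-mutation catalogs on a 60 kb
reference per planted fraction for recovery; 10,000 core-derived reads for
cross-assignment; 11,000–12,000 reads per abundance-ratio point; 200
cohort replicates of 100 samples for correlation-sign recovery. The
acceptance script uses 100 null samples and the same sizes otherwise.

## Known limitations

* The minimum estimate is a conservative lower bound with fraction-dependent
  bias (see above); it should not be read as an unbiased APOBEC mutation
  count, especially in weakly mutated samples.
* Unique-region boundaries are resolved only to about half the smoothing
  window; reads near true homology breakpoints may be conservatively
  unassigned.
* The unambiguous quantifier discards most of the library (everything
  outside unique regions), trading efficiency for specificity; its variance
  at low expression is correspondingly high, which the +0.5 pseudocount
  regularizes but does not remove.
* The enrichment test treats mutations as independent; clustered
  hypermutation violates this and can overstate significance.
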