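# Methods

`amperr` characterizes sequencing errors in high-coverage amplicon data of
the kind produced by flow-based pyrosequencers (the GS Junior HLA-typing
setting): several loci amplified with locus-specific primers, one pooled
library sequenced in multiple independent runs, and a truth set of expected
variants known in advance from Sanger sequencing. Because the original raw
data is not redistributable, the package pairs the analysis pipeline with a
synthetic read generator that reproduces the statistical structure the
analysis assumes, together with per-read ground truth, so every stage can
be validated end to end.

## The analysis pipeline

**Primer trimming.** Reads must begin with one primer and end with the
reverse complement of the other (either orientation), with at most one
mismatch per primer. Reads shorter than the two primers combined, or with
unrecognizable primer ends, are rejected and tallied.

**Alignment.** Each trimmed read is aligned semi-globally to its amplicon
reference: the full read is consumed, reference overhangs at either end are
free. Scoring is affine — match +2, mismatch −3, gap open −5, gap extend
−2, where a length-k gap costs `open + (k−1)·extend`. The dynamic program
is Biopython's `PairwiseAligner` (C implementation); both orientations are
tried and the higher score kept. A post-pass shifts every indel to its
leftmost placement within a homopolymer, so that recurrent errors at the
same run share one canonical coordinate. Alignments scoring below a
configurable floor are flagged unalignable. The tests check the aligner
against an independent brute-force Gotoh implementation on all read/
reference pairs up to 12 bp of a fixed enumeration set.

**Exon clipping.** Only exon sequence enters the statistics (intron
annotation is unreliable for these loci, and primer/flank bases are not
analysis targets). Columns outside the annotated exon interval are dropped;
an insertion at the exon boundary is kept iff its left reference neighbour
is inside the exon. Clipping is idempotent.

**Event extraction.** A maximal run of same-type discrepant columns is one
event: adjacent mismatches merge into a multi-base substitution, gap runs
into one insertion/deletion; mixed-type adjacent discrepancies stay
separate so per-type rates remain additive. The event identity key used for
truth comparison and cross-run intersection is
`(amplicon, left-aligned reference position, type, inserted/substituted
bases — or length for deletions)`. An insertion's reference position is the
first reference base after the fully left-aligned inserted segment, i.e.
the homopolymer run start. Deletions have no read base; their site quality
is the error-rate-space mean of the two flanking read bases (a convention —
nothing in the underlying assay defines it).

**Classification.** An event key found among the sample's expected variants
is a `true_variant`; one among the known systematic differences of a
co-amplified homologous locus (e.g. a pseudogene amplified alongside one
locus) is a `pseudogene_product`; everything else is an `error`. The
partition is a total function of the key, hence idempotent and
order-independent.

**Profiling.** The total error rate is erroneous bases / analyzed exon
bases, where an event of length L contributes L bases (for deletions, the
deleted reference bases) and the denominator counts read bases inside
exon-clipped alignment columns. Also reported: per-type rates and mean
event lengths, the fraction of reads with ≥1 error, errors per erroneous
read (both per-occurrence and distinct-key tallies — published totals are
ambiguous about which is meant, so both are kept), the cross-run
reproducible fraction (base mass of event keys present in every run over
all erroneous bases), coverage-normalized positional error histograms with
a weighted median, and per-run read/base summaries. Machine output keeps
full precision; percent rounding (2 decimals for rates, 1 for read
fractions) is presentation-only.

**Quality analytics.** All quality averaging happens in error-rate space:
Q = −10·log₁₀(p), scores are converted to probabilities, averaged, and
converted back. The neighborhood of an error is its `n_neighbors` (default
5) nearest read bases excluding the event's own bases, ties broken
upstream; events at read ends use what is available and are flagged
truncated. Homopolymer context of an error is the longest maximal run
overlapping the event span widened by `adjacency_window` (default 1 base,
matching an "at or adjacent" reading; window 0 gives the strict per-base
notion). Enrichment of error contexts over the references' background
run-length composition is a chi-square goodness-of-fit test with
low-expectation classes (< 5 expected) pooled rightward-to-leftward, never
below two classes. The run-length/quality relation is summarized by Pearson
correlation on (context length, event-site Q) pairs. Calibration tables bin
bases by integer reported Q and compare with −10·log₁₀(observed error
fraction) per bin; bins with no observed errors are flagged rather than
imputed.

## The synthetic read generator

The generator's defaults are the study conditions of the assay being
emulated; they are fixed once and the tests measure against them.

**References.** Each amplicon is `primer (20 bp) | flank (15 bp) | exon |
flank (15 bp) | primer (20 bp)`; three amplicons of 270 bp exons stand in
for a six-locus HLA panel (count and sizes configurable). Exon sequence is
drawn with a homopolymer-enriched Markov chain: repeat probability
`0.25 + 0.08·weight` (weight 1 by default), damped by 0.7 per base beyond
run length 3 and capped at 7 — matching the run-length range of real HLA
exon targets, where runs beyond ~7 bases do not occur. With weight 0, runs
of ≥4 are excluded. One allele per amplicon carries the sample's true
variants (default 2 isolated substitutions); one locus is co-amplified with
a pseudogene (default 25% of its reads) differing at ≥3 positions.

**Error model.** Substitutions are Bernoulli per base at a rate modulated
along the read by the quality profile but normalised so the mean over read
positions equals `substitution_rate` (default 0.05% — the assay's
substitution share). Indels are drawn per traversed homopolymer base with
probability `indel_base_rate · slope^(L−1)` for a run of length L (defaults
0.00023 and 1.9, chosen so the realized indel load over the default
references is ≈0.13% of bases, split ~2:1 insertions:deletions via
`indel_insertion_fraction` = 0.69, mirroring the assay's 0.09%/0.04%
insertion/deletion rates at a total error rate of ≈0.18%). Successes within
one run coalesce into a single over/undercall placed at the run's leftmost
base — the same left-alignment canon the extractor uses, which is what
makes truth and extraction directly comparable.

Three guards keep the injected truth alignment-unambiguous by construction:
allele/pseudogene variants are isolated substitutions placed away from runs
longer than 2 and never equal to a neighbouring base; injected events keep
≥2 matched anchor bases from any known difference position; and two indels
in one read must have ≥3 homopolymer runs between them (closer opposite-
sense pairs re-align as substitutions at run boundaries — the classic
pyrosequencing frame-shift degeneracy). Without these guards the optimal
alignment legitimately differs from the injected event list for a few
percent of reads; with them, extraction matches truth exactly away from
exon boundaries, which is what the oracle-equivalence test asserts.

**Quality model.** True per-base quality is the phred transform of the
base's total modeled error probability: the positional substitution risk
(piecewise-linear profile — ramp over the first 20 bases from Q33 to a Q37
plateau, decay after 300 bp toward Q25, echoing the characteristic late-
read quality drop) plus the homopolymer indel risk of the run the base sits
in, computed on the read itself. The latter produces the negative
run-length/quality correlation seen in flow-based data. Reported quality is
true quality, minus `error_site_q_penalty` (default 5) at injected error
sites (the "quality valley" at errors), passed through a configurable
miscalibration (default: +3 above Q30, −2 below — an instrument that
overestimates its best bases), rounded and clamped to integer [0, 40].

Two artifacts of these modeling choices are worth knowing. First, the
deterministic error-site penalty displaces *every* realized error out of
its original quality bin, so the calibration table of a default-config run
conditions on the penalty and is not a clean instrument-calibration
measurement; calibration is measured with the penalty disabled (as the
calibration tests and the worked example do). Second, primer bases never
receive errors, so calibration over whole raw reads is diluted by the
primer fraction; calibration measurements use insert bases only.

**Determinism.** All randomness flows from `numpy.random.default_rng`
seeded by `(seed, salt, run_index)`; identical configuration and seed give
byte-identical FASTQ/TSV/JSON outputs.

**What the generator does not emulate.** No flowgram/SFF signal model, no
emulsion-PCR duplicates or chimeras, no read-length distribution (reads
span their full amplicon; the real assay's length spread is not modeled),
no quality "peaks and valleys" tied to library-specific motifs beyond the
homopolymer term, and no PCR polymerase errors as a separate class.
Passing tests therefore demonstrate that the pipeline measures the modeled
structure correctly — not that real GS Junior data would yield these exact
numbers.

## Problem sizes used in tests

The test suite validates statistical claims at the smallest sizes where the
assertions are sharp: parameter recovery profiles ≈10⁶ exon bases (two runs
of 640 reads per amplicon) against 3-binomial-SD bands; oracle equivalence
aligns >10⁴ reads and requires precision = recall = 1.0 for events ≥12 bp
from exon boundaries (events straddling the clip boundary have no single
well-defined coordinate); calibration recovery uses 10⁶ bases per
miscalibration scenario; the association test's type-I rate is estimated
over 500 replicates of 1000 uniformly placed errors (with adjacency window
0, where the uniform null's class distribution is exactly the per-base
background — with window 1 adjacency inflates long classes and the
comparison would be against a mismatched null).

## Known limitations

- Alignment-representation ambiguity is avoided in simulation rather than
  resolved in extraction; real data contains genuinely ambiguous events and
  their coordinates depend on the aligner's tie-breaking.
- The correction hook reports before/after erroneous-read fractions for a
  stub or external corrector; no error-correction algorithm is included.
- Chi-square pooling keeps ≥2 classes even when an expected count stays
  below 5; p-values in that regime are approximate.
- The per-occurrence vs distinct-key errors-per-read means can differ
  substantially at high systematic-error rates; consumers should pick the
  tally matching their question.
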