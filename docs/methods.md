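# Methods

## Coordinates and strand

All internal coordinates are 0-based half-open on the forward strand of
each sequence; conversion to 1-based inclusive (BLAST tabular, GFF3) or
reversed-pair strand encoding happens only at the I/O boundary
(`estmap.io`). Strand is a property of the query/target pair, as in PSL:
target coordinates are always forward-strand and `-` means the query
matches the reverse complement. One degenerate case of BLAST tabular
coordinates is worth noting: a 1 bp interval is palindromic in 1-based
inclusive form and cannot encode strand, so round-trip identity is only
guaranteed for intervals of length ≥ 2.

PSL identity is computed as matches / (matches + mismatches); BLAST
tabular identity is taken from column 3, with an optional 13th column read
as the positives (similarity) percentage used by the annotation filter.

## HSP filtering and collinear chaining

Round 1 keeps HSPs with identity strictly above 90% and length strictly
above 50 bp; round 2 optionally drops HSPs whose query is a singleton
read. All five headline thresholds of the pipeline (90% identity, 50 bp
HSP length, 100 bp chain coverage, 80 bp annotation-HSP length, 80%
annotation similarity) are deliberately strict inequalities — a value
exactly at the bound is rejected — so boundary behaviour is unambiguous
and testable. The known-gene screen (e-value ≤ 0.001, identity > 80%,
length > 50 bp) treats the e-value as a ceiling.

Collinearity is joint monotonicity: within a (query, target, strand)
group, HSP *b* may follow *a* when the query order and the target order
agree (target order reversed on `-`), with strictly increasing interval
ends and pairwise overlap at most `overlap_tol` (default 10 bp) on either
side. The chain extracted is the subset maximizing query coverage (union
of query intervals), found by dynamic programming over the query-sorted
HSPs; because chain ends are monotone, the coverage gain of appending an
HSP depends only on its immediate predecessor, so the DP is exact. The
procedure repeats on the leftovers, so chaining is a partition of the
filtered HSPs. A brute-force subset search validates the DP on small
instances in the test suite.

## The ten-way classification

Categories A (transcript with no retained HSP) and B (genome contig with
no retained HSP) count sequences. Within a chain, each adjacent HSP pair
with query gap `qg` and strand-aware target gap `tg` is classified by the
trichotomy: intron-like E when `tg > gap_tol` and `qg ≤ gap_tol`;
transcript-side gap D when `qg > gap_tol` and `tg ≤ gap_tol`; F when both
exceed `gap_tol`; otherwise G (contiguous/overlapping HSPs merging into
one segment). `gap_tol` defaults to 10 bp: large enough to absorb
alignment slop, far below realistic intron lengths (hundreds of bp).
D is read as a gap in the *transcript* assembly (genomic continuity,
missing transcript sequence); the converse reading would be
indistinguishable from E.

Terminal overhangs C (left) and J (right) require at least 1 bp of
unaligned query beyond the chain and the flanking HSP ending within
`end_tol` (20 bp) of the corresponding target terminus, with the edge
test mirrored on `-` chains. H (putative intergenic interval) is the
target distance between the chain spans of two *different* queries
adjacent on the same contig. I (scaffold join) is a query whose chains
fall on two or more targets with disjoint query intervals; adjacent
target pairs in query order each yield one join edge.

A query classified as I is not additionally tested for C/J: planted join
evidence necessarily sits at contig edges, and counting it twice would
make the category table ambiguous. This is the one place where the
categories are given a precedence.

Univocal 1-to-1 selection requires a chain of ≥ 2 HSPs covering > 100 bp
of the transcript, every member HSP above the round-1 thresholds, and all
qualifying chains of the transcript on a single genome contig
(query-side univocality; the target may host several transcripts, which
matches genes sharing a contig).

## Intron inference and splice sites

For each E-gap of a univocal chain, both boundaries are shifted jointly
by δ ∈ [−12, +12] (length-preserving) to maximize an ordered motif score:
GT–AG and AT–AC score 2, GC–AG scores 1, anything else 0. Ties break
toward δ = 0, then the smallest |δ| (positive before negative), so an
absent motif leaves the aligner's boundary untouched. Gaps shorter than
4 bp are discarded. This bounded local search stands in for a full
spliced-alignment DP; it is exact whenever the true junction lies within
the window and no competing canonical pair does, which the synthetic
generator guarantees by construction.

Donor/acceptor dinucleotides are clipped after reverse-complementing the
genomic segment for `-` chains. Typing is by terminal dinucleotides only:
GT–AG → U2, AT–AC → U12, GC–AG → a flagged noncanonical U2 variant
(reported separately rather than pooled), anything else → other. No
branch-point or polypyrimidine model is attempted.

PWM windows default to 3 exonic + 6 intronic bases (donor) and 6 intronic
+ 3 exonic (acceptor); the widths are configurable since they are a
gene-finding convention, not a measurement. Frequencies use no
pseudocount and exclude N from each column's denominator; information
content is `2 + Σ_b p log2 p` bits under a uniform background, with an
optional background-frequency argument giving relative entropy instead
(relevant for A/T-rich genomes, where uniform-background IC overstates
A/T-rich positions).

## Assembly census

Fragment ids (`read_12`-style suffixes) are collapsed once, rightmost
suffix only. A read counts as a contig member in an assembly if any of
its fragments was assembled into a contig there; singleton only if all
fragments stayed singletons. Within a Venn region, a read is reported as
contig/singleton when its state agrees across every member assembly and
as mixed otherwise. GC% excludes ambiguity codes from numerator and
denominator; the median of an even-sized set is the mean of the two
central values; quartiles use linear interpolation.

## ORFs and consensus TM calling

Six-frame translation uses the standard genetic code (ambiguous codons →
X, trailing partial codon dropped); the longest ORF is the longest
stop-free segment across frames, with ties broken by frame order then
leftmost start. A start-codon-anchored mode (`require_start`) is provided
but off by default, since fragment ESTs routinely lack 5′ ends. The
minimum ORF length is 30 aa.

The built-in predictor slides a 19-residue Kyte–Doolittle window;
maximal runs of window means above 1.6, separated by ≥ 5 residues, each
count as one TM segment. Signal peptides are hydrophobic and mimic TM
segments, so they are removed (N-terminal truncation) before the second
and third predictor passes; the first pass reports them. Consensus
accepts a protein when ≥ 2 predictors report ≥ 1 TM segment. Redundancy
removal greedily keeps the longest accepted sequence and marks a shorter
one redundant when a semi-global (infix) edit-distance alignment places
it inside a kept sequence at ≥ 95% identity; infix alignment spans the
whole shorter sequence, so the 90% coverage requirement is implied. The
identity/coverage cutoffs are exposed as parameters.

## GO rollup

Annotation HSPs pass at length > 80 bp, similarity > 80% and e-value
≤ 1e-25 (the e-value default is configurable; the printed form is
ambiguous between 1e-24 and 1e-25). Passing hits transfer the union of
their proteins' GO terms to the query, each term requiring support from
at least `min_support` hits (default 1) — a deliberate simplification of
evidence-weighted annotation scoring, which depends on unpublished
weights; the rollup arithmetic downstream is independent of that choice.
Terms propagate over is_a edges only. A term's level is 1 + its shortest
is_a path to the namespace root; each query is counted once per distinct
level-2 ancestor, so one query may appear under several rows. Excluded
(over-represented) classes are reported separately and omitted from the
normalization total; `freq_pct` rows therefore sum to 100% of the
non-excluded annotations.

## Synthetic data: what it does and does not emulate

The generator samples i.i.d. background nucleotides with
P(G) = P(C) = gc_target/2 (default 0.35, the A/T-rich regime), plants one
scenario per genome contig (two contigs per scaffold join) with pads
larger than `end_tol` around interior genes, and emits the exact
exon-to-genome HSP table implied by construction — identity 100 minus the
configured jitter. Introns are GT–AG, or AT–AC with probability
`u12_fraction` (default 0.05); about half the multi-exon genes are placed
on the minus strand. Around every planted junction, a ±20 bp zone is kept
free of competing canonical splice pairs: the refinement window (12 bp)
plus the largest boundary perturbation studied (8 bp), so the refinement
optimum is unique. Proteins are hydrophilic backbones with planted
21-residue hydrophobic TM segments and optional N-terminal signal
peptides.

It does not emulate read-level sequencing error, quality values,
assembly chimerism, repeats, paralogy, or alignment noise beyond
coordinate perturbation and substitution jitter — so passing tests
demonstrate the correctness of the classification/refinement logic under
its stated definitions, not robustness to every artefact of real
aligner output.

## Problem sizes and determinism

The shipped study conditions are desk-scale: the scenario-recovery mix
plants 33 scenarios (10 introns); the splice study plants 500 introns
with boundaries perturbed by up to ±8 bp; oracle-equivalence checks run
100 randomized instances per operation at sizes where exhaustive
computation is feasible (chains of ≤ 10 HSPs, 10–12-term ontologies).
All randomness flows from a single integer seed through
`numpy.random.default_rng`; the full pipeline writes byte-identical
reports across runs with the same seed, which the test suite asserts
file by file.
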