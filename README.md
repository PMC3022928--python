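# estmap

Reconciling a transcriptome assembly with a fragmented draft genome.

When an EST/454-style transcript set is aligned to a draft genome with a
local aligner (BLAT-style HSP tables), every transcript/contig relationship
falls into one of a small number of patterns: transcripts absent from the
genome (novel sequence), genome contigs without transcript evidence,
transcripts overhanging a contig edge (extensions), genome-side gaps
bridged by a contiguous transcript (introns), transcript-side gaps
(assembly gaps), overlapping HSPs, intergenic spacing between genes, and
transcripts split across two contigs (scaffold-join evidence). `estmap`
implements that reconciliation as a reusable, tested pipeline:

- **I/O and coordinates** (`estmap.io`) — FASTA, PSL and BLAST tabular
  (`-outfmt 6`) readers with every coordinate normalized to 0-based
  half-open on the forward strand, plus GFF3 output for inferred introns.
- **Filtering and chaining** (`estmap.reconcile`) — two-round HSP
  filtering (identity > 90%, length > 50 bp; then singleton removal),
  maximum-coverage collinear chaining by dynamic programming, the ten-way
  A–J classification, per-set coverage, univocal 1-to-1 transcript/contig
  selection (≥ 2 collinear HSPs covering > 100 bp), and the scaffold-join
  graph.
- **Splice sites** (`estmap.splice`) — intron boundary refinement by a
  bounded joint shift maximizing a splice-motif score
  (GT–AG = AT–AC > GC–AG), strand-corrected donor/acceptor clipping,
  U2/U12 typing by terminal dinucleotides, and position weight matrices
  with per-position information content
  `IC = 2 + Σ_b p_b log2 p_b` (bits, uniform background).
- **Assembly census** (`estmap.census`) — read-identifier
  canonicalization (fragment-suffix removal), three-way membership Venn
  with contig/singleton breakdown, GC% and length statistics.
- **ORFs and membrane proteins** (`estmap.orf`) — six-frame translation,
  longest stop-free ORF extraction, parsers for three topology-predictor
  summary dialects, a built-in Kyte–Doolittle hydropathy caller,
  signal-peptide masking, 2-of-3 consensus voting and redundancy removal.
- **GO rollup** (`estmap.gorollup`) — annotation-HSP filtering
  (length > 80 bp, similarity > 80%, e-value ≤ 1e-25), term transfer,
  is_a ancestor propagation and fixed-level frequency tables with
  configured over-represented classes excluded from the total.
- **Synthetic data** (`estmap.simulate`) — a seeded generator planting
  every scenario with recorded ground truth (A/T-rich ~35% GC genome,
  GT–AG/AT–AC introns, TM proteins with signal peptides), so each stage
  is testable without any external dataset or aligner.

## Worked example

```
estmap demo --seed 2 --out demo_out
```

simulates a dataset with one instance of each scenario (four introns),
runs the whole pipeline, writes the reports into `demo_out/` and prints a
summary such as:

```
{
  "category_counts": {"A": 1, "B": 1, "C": 1, "D": 1, "E": 4,
                      "F": 1, "G": 1, "H": 1, "I": 1, "J": 1},
  "coverage_query_pct": 79.4549,
  "coverage_target_pct": 26.154,
  "n_one_to_one": 7,
  "n_introns": 4,
  "join_edges": 1,
  "tm_accepted": 20,
  "tm_nonredundant": 20
}
```

The category counts equal the planted scenario counts; the four genome
gaps bridged by transcripts are reported as introns with refined
boundaries in `demo_out/introns.gff3` and splice-site windows in
`demo_out/sites.tsv`; U2 donor/acceptor PWMs (frequencies plus
information content per position) land in `demo_out/pwm_u2_*.tsv`.

The same stages are available on real files: `estmap reconcile --hsps
map.psl --dialect psl --genome g.fa --transcripts t.fa --out dir/`,
`estmap venn`, `estmap orftm`, `estmap gorollup` (see `--help`).

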