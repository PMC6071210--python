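# Methods

## Coordinates and inputs

All internal coordinates are 0-based half-open; GTF (1-based closed) is
converted at the parsing boundary, BED is native. Only `exon` features
with `gene_id`/`transcript_id` attributes are read; exon chains are kept
in transcript 5′→3′ order (descending genomic coordinate on the minus
strand) and introns are the gaps between consecutive exons. "Left" and
"right" flank labels of a cluster always refer to pre-mRNA 5′→3′ order,
so they are genomically reversed for minus-strand genes. Conserved
elements are treated as a strandless merged interval mask; their score
and name columns are ignored. N bases are legal in inputs; any folding
window containing an N is skipped (logged), but N positions count toward
interval length in coverage fractions.

## MXE calling on the splicing graph

The splicing graph has splice sites as nodes and exons/introns of the
annotated transcripts as edges; identical coordinates merge into one
edge carrying the union of supporting transcript ids, so the graph is
invariant under duplicated or reordered annotations. A cluster is a node
pair (u, v) joined by ≥ 2 vertex-independent intron–exon–intron paths.
Because a 3-edge path is internal-node-disjoint from another exactly
when their middle exons share no splice site, the maximum independent
set is computed exactly by grouping middle exons that share a splice
site (union–find) and counting groups; the shortest exon represents its
group. Candidate pairs are enumerated per gene and strand; a candidate
whose variable-exon set is identical to an already-kept, genomically
wider candidate is suppressed, which separates nested/overlapping
candidates deterministically. Where several exon edges flank u or v the
shortest is recorded. The graph-only definition does not ask whether any
single transcript contains two variable exons; a `strict` flag adds that
filter (off by default). Variable exons that overlap but share no splice
site count as distinct, but such candidates leave no genomic gap introns
and are not materialized as clusters.

## Similarity

σ(x, y) = s(x, y) / max{s(x,x), s(y,y)} with local Smith–Waterman scores
(match +1, mismatch −0.2, gap open −1, gap extend −0.5, i.e. a gap of
length k costs 1 + 0.5(k−1)); scoring is delegated to Biopython's
`PairwiseAligner`, and an exhaustive alignment-path enumerator serves as
the independent oracle in the tests. σ lies in [0, 1], is symmetric, and
equals 1 for identical sequences. Sequences longer than 10,000 nt are
excluded. The length-matched control pool contains every distinct
annotated intron genome-wide, sorted by length; a control is drawn by
perturbing the query's rank by a uniform non-zero offset in ±10, clamped
to the pool, never returning the query itself. Δσ replaces *both*
introns of a pair with independently drawn controls (replacing only one
is available by flag). For the exon–intron comparison, the intron pair
(i, i+1) is associated with variable exons 2.i and 2.(i+1); the first
pair (0, 1) has no exon counterpart and carries NA.

## Dinucleotide-preserving shuffle

A move picks an interior position i uniformly, then a partner j
uniformly among interior positions with the same outer letters
(seq[j−1] = seq[i−1], seq[j+1] = seq[i+1]) and |j − i| ≥ 2, and swaps
the middle letters; l such moves are attempted for a sequence of length
l, no-ops included. Each legal move conserves the overlapping
dinucleotide counts exactly, hence also the mononucleotide counts; the
first and last letters never move. Partners overlapping the pivot
(|j − i| < 2) must be excluded because exchanging the middles of
overlapping triplets changes dinucleotide counts; this constraint is
part of the move definition here. Positions are sampled with
replacement. The kernel is a numba routine with per-context position
buckets, so a move costs O(context size) at worst.

## Duplex engine

The built-in engine minimizes over all intermolecular duplexes: chains
of base pairs (Watson–Crick and G·U) grouped into helices of stacked
pairs, separated by interior/bulge loops, plus one duplex initiation
penalty (4.09 kcal/mol). Helix stacks use the standard nearest-neighbor
Watson–Crick free energies at 37 °C; stacks containing one or two wobble
pairs use flat approximations (−1.3 / −0.5 kcal/mol). Loops are charged
an opening penalty (3.0 kcal/mol) plus 0.3 kcal/mol per unpaired base,
with at most 30 unpaired bases per loop — a larger gap means two
separate candidate duplexes, of which the DP reports the better. A pure
per-base loop charge without the opening term was rejected: it lets the
optimum chain arbitrarily many 2-stack helices, so random 300-nt
backgrounds reach ≈ −200 kcal/mol and drown a planted 20-bp arm; with
the opening term the background scale is comparable to standard duplex
folders. Lonely (single-pair) helices are forbidden by default
(`no_lonely_pairs`). The DP is O(n·m·L²) with L = 31 (numba kernel) and
is checked exactly against full structure enumeration on 8-mers. Ties
are broken toward the 5′-most closing pair on the first sequence.
Intramolecular structure (the accessibility/opening-energy term of
RNAup-class models) is out of scope, so absolute ΔG values are
engine-specific; all conclusions rest on ΔΔG against matched controls.
An adapter can call an installed RNAduplex/RNAplex-style executable and
parse its plain-text output into the same (ΔG, sites) convention.

ΔΔG = ΔG(x, y) − ΔG(control(x), control(y)), controls being either
dinucleotide-preserving shuffles (default) or length-matched draws from
a pool. One control replicate is used by default; `n_controls` > 1 takes
the median control energy. Records with |ΔΔG| > 30 kcal/mol are
discarded (both tails, applied literally) and excluded from downstream
statistics. Cluster scans fold the concatenation of each intron's
conserved parts (segments ordered 5′→3′ of the pre-mRNA, reverse
complemented on minus-strand genes) and map duplex sites back to genomic
coordinates through the segment map; per flanking intron, sites from
different internal partners are merged into docker records scored by the
number of supporting partners.

## Statistics

All p-values are one-sided, with directions fixed by the biological
hypotheses: conservation of cluster introns greater than controls
(Mann–Whitney), Δσ greater than zero and ΔΔG less than zero (Wilcoxon
signed-rank, zero differences dropped), exon–intron similarity
correlation positive (Pearson r with t = r√((n−2)/(1−r²)) on n−2 df).
Rank tests use the normal approximation with tie correction and no
finite-population or continuity correction; degenerate inputs (all tied,
all zero) report p = 0.5. No multiple-testing correction is applied —
the report carries raw one-sided p-values. Type-I error calibration of
all three tests is asserted in the suite (5% ± 1.5% at α = 0.05 over
5,000 null datasets).

## Synthetic cohorts

A positive gene starts from a three-exon ancestor whose intron upstream
of the middle exon carries a stem-loop: docker arm `a` (20 nt), loop
(30 nt), and `a′` = reverse complement of `a`, inside a 600-nt intron;
exons are 90 nt, base composition i.i.d. at GC 0.45. The duplicated
block runs from the breakpoint just 5′ of `a′` to a breakpoint inside
the downstream intron, chosen so that every intron of the product is
600 nt; the block is copied in tandem `n_duplications` times (default 2,
so clusters have three exons and every pair class is populated — most
real clusters have two exons, but a two-exon cluster has no
internal–internal pair at all). In the bidirectional mode the downstream
intron also carries a stem-loop (`b′ … b`) and the block spans
[a′ … exon 2 … b′], leaving one b-arm upstream of one a-arm in every
middle intron, docker `a` in the left and docker `b` in the right
flanking intron. Each copied block is mutated by i.i.d. substitutions
(no indels, keeping ground-truth coordinates exact); the per-gene rate
is the configured mean (default 0.05) scaled by a uniform 1 ± 0.75 factor so
clusters differ in age — age variation is what produces a positive
exon–intron similarity correlation across a cohort. Breakpoint jitter is
available (default 0). Each gene sits on its own contig with 100-nt
margins and a random strand; minus-strand genes store the reverse
complement, exercising all strand-handling code. Positive genes carry
one extra constitutive exon and intron upstream of the cluster so that
"a random intron of the same gene" exists outside the cluster. Null
genes have four exons, introns of 450–750 nt, and two identical
transcripts. The conserved track marks every planted arm ± 5 nt plus
~10% random decoy intervals in random introns. Annotation emits one
isoform per variable exon.

What the generator does *not* emulate: splice-site motifs, codon
structure, indels, transposon-mediated duplication mechanisms,
co-transcriptional folding kinetics, and real conservation tracks (whose
elements are longer and denser than arm ± 5 nt). Consequences for
interpretation: passing tests show the pipeline recovers the planted
docker–selector geometry under point-substitution divergence; they do
not establish performance on real annotations, where intron lengths,
conservation structure and cluster sizes are far more heterogeneous.
One genuine property of the model worth noting: selector arms of one
cluster are identical by descent, so internal–internal intron pairs
share chance self-complementary motifs and show a small *real* excess
propensity to hybridize relative to shuffled controls (about
−1.5 kcal/mol for fresh 30-nt copies; the same shift is reproduced by an
independent duplex folder). On real, anciently diverged clusters this
internal–internal signal is expected to vanish, and its near-absence is
the relevant negative control there.

## Problem sizes and determinism

Default analysis scales: cohorts of 50 positive + 50 null genes, introns
of ~600 nt, conserved concatenations of tens of nt; the full pipeline on
such a cohort takes a few seconds. Every stage draws randomness from an
explicit seed (`numpy` `SeedSequence` children per stage), and re-running
with identical inputs, config and seed reproduces all output tables
byte-identically. Degenerate inputs are defined rather than erroneous:
single-exon transcripts have no introns; empty conserved concatenations
skip the pair (logged); an empty cluster set yields a report of NA rows.
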