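# mxefold

Analysis of **mutually exclusive exon (MXE) clusters** and the competing
RNA secondary structures that regulate them, for people working on
alternative splicing in annotated genomes (fly, human, or any organism
with a GTF + genome FASTA + conserved-element BED).

In many genes a tandem array of exons is spliced so that exactly one
exon of the array appears in each mature transcript. The best-studied
mechanism relies on RNA structure: a conserved intronic **docking site**
is complementary to several **selector sequences**, one per variable
exon; only one docker–selector duplex can form at a time, and the
pairing that forms decides which exon is exposed to the spliceosome.
`mxefold` implements the full computational chain for studying this
arrangement, plus a generator for the evolutionary model that explains
it: a genomic duplication that copies an exon together with **one arm of
an intronic stem-loop**, instantly creating two selectors competing for
the same docker.

## What it computes

1. **MXE cluster detection** (`mxefold detect-mxe`). The annotation is
   turned into a splicing graph — a bipartite graph whose nodes are
   splice sites and whose edges are exons or introns. A node pair joined
   by *n* ≥ 2 vertex-independent paths of the form intron–exon–intron is
   an MXE cluster of *n* exons 2.1…2.n, with n+1 intervening introns
   numbered 0 (left) … n (right) in pre-mRNA 5′→3′ order.
2. **Conservation** (`mxefold conservation`). For each cluster intron,
   the fraction of bases inside conserved elements (e.g. UCSC
   phastConsElements), against a randomly chosen intron of the same gene
   (one-sided Mann–Whitney).
3. **Similarity** (`mxefold similarity`). For consecutive cluster
   introns x_i, x_{i+1}, the normalized local-alignment similarity

       σ(x, y) = s(x, y) / max{ s(x,x), s(y,y) }

   with Smith–Waterman scores (match 1, mismatch −0.2, gap open −1, gap
   extend −0.5; sequences over 10,000 nt excluded), and
   Δσ = σ − σ₀ against a length-matched control pair (pool sorted by
   length, rank perturbed by at most ±10). One-sided Wilcoxon on Δσ.
4. **Hybridization** (`mxefold hybridize`). Intermolecular duplex
   minimum free energy between the conserved parts of intron pairs
   (left-flank vs internal, internal vs internal, internal vs
   right-flank), with a nearest-neighbor duplex dynamic program
   (Watson–Crick + G·U stacks, interior/bulge loops, no lonely pairs).
   The statistic of record is ΔΔG = ΔG(true pair) − ΔG(control pair),
   where controls are dinucleotide-preserving shuffles or length-matched
   introns; records with |ΔΔG| > 30 kcal/mol are discarded. Predicted
   docker sites are exported as BED. An adapter
   (`mxefold.duplex.external_duplex_mfe`) can substitute an installed
   RNAduplex/RNAplex-style executable.
5. **Synthetic cohorts** (`mxefold simulate`). Genes evolved under the
   duplication model — unidirectional (one stem-loop arm copied, so all
   selectors compete for a single upstream docker) or bidirectional
   (arms of two independent stem-loops
   copied, leaving a b-arm upstream of an a-arm in every middle intron)
   — with point mutations at a configurable rate, plus null genes, a
   conserved-element track marking the planted arms, and a ground-truth
   table. Everything the pipeline needs, with known answers.

## Worked example

```sh
mxefold simulate --n-pos 10 --n-null 10 --seed 7 --outdir demo
mxefold all --gtf demo/annotation.gtf --fasta demo/genome.fa \
            --bed demo/conserved.bed --outdir demo/out --seed 1
```

prints (exactly, given these seeds):

```
                 comparison         test direction  n statistic p_one_sided
conservation_mxe_vs_control mann_whitney   greater 80       970    0.048329
        delta_sigma_gt_zero     wilcoxon   greater 30       423 4.45936e-05
         ddg_L_to_i_lt_zero     wilcoxon      less 20         0 4.42873e-05
         ddg_i_to_j_lt_zero     wilcoxon      less 10        20    0.222293
         ddg_j_to_R_lt_zero     wilcoxon        NA  0        NA          NA
exon_intron_similarity_corr    pearson_t   greater 20 -0.014012    0.523377
```

Reading it: all 10 planted clusters are detected; their flanking introns
are more conserved than random same-gene introns (p ≈ 0.048 at this
small cohort size); consecutive cluster introns are more similar than
length-matched controls (Δσ > 0, p ≈ 4×10⁻⁵); the left flanking intron
has a strong excess propensity to base-pair the internal introns
(ΔΔG < 0, p ≈ 4×10⁻⁵) while internal–internal pairs show no comparable
signal — the docker–selector signature. The `j_to_R` row is NA because
unidirectional clusters plant no arms in the right intron and its
conserved concatenation is usually empty. `demo/out/` also contains the
full `clusters.tsv`, `cons.tsv`, `sim.tsv`, `ddg.tsv` and
`docker_sites.bed` tables; re-running with the same seed reproduces them
byte for byte.

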