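"""Synthetic cohorts implementing the tandem-duplication model of MXE
origin.

Each positive gene starts from an ancestral three-exon gene whose intron
upstream of the middle exon carries a stem-loop: a docking arm ``a`` and
its reverse complement ``a'`` separated by a loop. A genomic duplication
copies the block [a' .. exon 2 .. part of the downstream intron] in
tandem, so every copy contributes one selector arm complementary to the
same docker — the arrangement found in mutually exclusive exon clusters.
In the bidirectional variant both flanking introns carry a stem-loop and
the duplicated block spans [a' .. exon 2 .. b'], leaving one a-arm and
one b-arm in every middle intron (b-arm upstream of a-arm) with dockers
``a`` in the left and ``b`` in the right flanking intron.

Copies are mutated by i.i.d. substitutions at a configurable rate after
duplication. Null genes have the same exon/intron geometry but no
duplication and no planted complementarity. The emitted conserved-element
track marks every planted arm (with padding) plus random decoy intervals,
so conservation contrasts are non-trivial.

Every output (genome FASTA, GTF, conserved BED, ground truth) is a pure
function of the cohort spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome import (
    GeneModelSet,
    GenomicInterval,
    IntervalSet,
    SequenceStore,
    Transcript,
    reverse_complement,
    write_gtf,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticCohortSpec:
    """Parameters of the duplication generator.

    The final cluster size is n = n_duplications + 1 variable exons.
    mutation_rate is the per-base substitution probability applied to
    every duplicated block. breakpoint_jitter shifts the duplication
    breakpoints by up to the given number of bases.
    """

    n_positive: int = 50
    n_null: int = 50
    mode: str = "unidirectional"  # or "bidirectional"
    n_duplications: int = 2
    exon_len: int = 90
    intron_len: int = 600
    arm_len: int = 20
    loop_len: int = 30
    mutation_rate: float = 0.05
    gc: float = 0.45
    seed: int = 1
    pad: int = 5  # conserved-element padding around each arm
    decoy_fraction: float = 0.1
    breakpoint_jitter: int = 0
    flank: int = 100  # contig padding around each gene
    # clusters differ in duplication age: each positive gene's substitution
    # rate is mutation_rate scaled by 1 +/- age_scatter (uniform)
    age_scatter: float = 0.75

    def __post_init__(self) -> None:
        if self.mode not in ("unidirectional", "bidirectional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.n_duplications < 1:
            raise ValueError("need at least one duplication")
        if min(self.exon_len, self.intron_len, self.arm_len, self.loop_len) <= 0:
            raise ValueError("all lengths must be positive")
        if 2 * self.arm_len + self.loop_len > self.intron_len:
            raise ValueError("stem-loop does not fit in the intron")


@dataclass
class GroundTruth:
    """Planted features of one synthetic gene, in genomic coordinates."""

    gene_id: str
    is_cluster: bool
    mode: str
    variable_exons: tuple[GenomicInterval, ...] = ()
    docker_arms: dict[str, GenomicInterval] = field(default_factory=dict)
    selector_arms: dict[str, GenomicInterval] = field(default_factory=dict)
    breakpoints: tuple[int, ...] = ()  # gene-space offsets of block copies


@dataclass
class Cohort:
    spec: SyntheticCohortSpec
    models: GeneModelSet
    store: SequenceStore
    elems: IntervalSet
    truths: dict[str, GroundTruth]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "bed": outdir / "conserved.bed",
            "truth": outdir / "truth.tsv",
        }
        self.store.to_fasta(paths["fasta"])
        write_gtf(self.models, paths["gtf"])
        self.elems.to_bed(paths["bed"])
        with open(paths["truth"], "w") as fh:
            fh.write("gene_id\tis_cluster\tmode\tn\tvariable_exons\t"
                     "docker_arms\tselector_arms\n")
            for gid in sorted(self.truths):
                t = self.truths[gid]
                ve = ",".join(f"{e.start}-{e.end}" for e in t.variable_exons)
                da = ";".join(f"{k}:{v.chrom}:{v.start}-{v.end}:{v.strand}"
                              for k, v in sorted(t.docker_arms.items()))
                sa = ";".join(f"{k}:{v.chrom}:{v.start}-{v.end}:{v.strand}"
                              for k, v in sorted(t.selector_arms.items()))
                fh.write(f"{gid}\t{int(t.is_cluster)}\t{t.mode}\t"
                         f"{len(t.variable_exons)}\t{ve}\t{da}\t{sa}\n")
        return paths


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        options = [b for b in "ACGT" if b != arr[i]]
        arr[i] = options[int(rng.integers(3))]
    return "".join(arr)


# A gene under construction: ordered (label, sequence) pieces in gene
# space (pre-mRNA 5'->3'). Labels: "exon:<name>", "arm:<name>", "seq".
Pieces = list[tuple[str, str]]


def _spans(pieces: Pieces) -> dict[str, tuple[int, int]]:
    spans = {}
    off = 0
    for label, seq in pieces:
        if label != "seq":
            spans[label] = (off, off + len(seq))
        off += len(seq)
    return spans


@dataclass
class AncestralGene:
    """Three-exon ancestral gene with planted stem-loop arm sequences."""

    exon1: str
    exon2: str
    exon3: str
    up_prefix: str  # intron 1: prefix, a, loop, a', suffix
    arm_a: str
    up_loop: str
    up_suffix: str
    down_seq: str  # intron 2 for the unidirectional mode
    # bidirectional only: intron 2 = prefix, b', loop, b, suffix
    down_prefix: str = ""
    arm_b: str = ""
    down_loop: str = ""
    down_suffix: str = ""

    @property
    def arm_a_prime(self) -> str:
        return reverse_complement(self.arm_a)

    @property
    def arm_b_prime(self) -> str:
        return reverse_complement(self.arm_b)


def make_ancestral_gene(
    spec: SyntheticCohortSpec, rng: np.random.Generator
) -> AncestralGene:
    E, I = spec.exon_len, spec.intron_len
    L, Lo = spec.arm_len, spec.loop_len
    prefix_u = I // 3
    suffix_u = I - prefix_u - 2 * L - Lo
    if suffix_u <= 0:
        raise ValueError("intron too short for the stem-loop layout")
    g = dict(
        exon1=_random_seq(E, spec.gc, rng),
        exon2=_random_seq(E, spec.gc, rng),
        exon3=_random_seq(E, spec.gc, rng),
        up_prefix=_random_seq(prefix_u, spec.gc, rng),
        arm_a=_random_seq(L, spec.gc, rng),
        up_loop=_random_seq(Lo, spec.gc, rng),
        up_suffix=_random_seq(suffix_u, spec.gc, rng),
        down_seq="",
    )
    if spec.mode == "unidirectional":
        g["down_seq"] = _random_seq(I, spec.gc, rng)
    else:
        prefix_d = I - 2 * L - suffix_u
        suffix_d = I - prefix_d - 2 * L - Lo
        if prefix_d <= 0 or suffix_d <= 0:
            raise ValueError("intron too short for the bidirectional layout")
        g.update(
            down_prefix=_random_seq(prefix_d, spec.gc, rng),
            arm_b=_random_seq(L, spec.gc, rng),
            down_loop=_random_seq(Lo, spec.gc, rng),
            down_suffix=_random_seq(suffix_d, spec.gc, rng),
        )
    return AncestralGene(**g)


def apply_unidirectional_duplication(
    gene: AncestralGene, spec: SyntheticCohortSpec, rng: np.random.Generator
) -> tuple[Pieces, tuple[int, ...]]:
    """Tandem-duplicate [a' .. exon 2 .. downstream part] n_duplications
    times and mutate every copy; returns the piece list and the
    gene-space offsets of the block copies."""
    n = spec.n_duplications + 1
    L, S = spec.arm_len, len(gene.up_suffix)
    d = spec.intron_len - L - S  # downstream bases inside the block
    if d <= 0 or d >= len(gene.down_seq):
        raise ValueError("duplication block exceeds the downstream intron")
    jitter = (int(rng.integers(0, spec.breakpoint_jitter + 1))
              if spec.breakpoint_jitter else 0)
    loop = gene.up_loop[: len(gene.up_loop) - jitter]
    loop_tail = gene.up_loop[len(gene.up_loop) - jitter:]
    block = [
        ("seq", loop_tail),
        ("arm", gene.arm_a_prime),
        ("seq", gene.up_suffix),
        ("exon", gene.exon2),
        ("seq", gene.down_seq[:d]),
    ]
    pieces: Pieces = [
        ("exon:1", gene.exon1),
        ("seq", gene.up_prefix),
        ("arm:a", gene.arm_a),
        ("seq", loop),
    ]
    breakpoints = []
    off = sum(len(s) for _, s in pieces)
    for k in range(1, n + 1):
        breakpoints.append(off)
        for label, seq in block:
            mutated = _mutate(seq, spec.mutation_rate, rng)
            if label == "arm":
                pieces.append((f"arm:a_sel_{k}", mutated))
            elif label == "exon":
                pieces.append((f"exon:var_{k}", mutated))
            else:
                pieces.append(("seq", mutated))
            off += len(seq)
    pieces.append(("seq", gene.down_seq[d:]))
    pieces.append(("exon:3", gene.exon3))
    return pieces, tuple(breakpoints)


def apply_bidirectional_duplication(
    gene: AncestralGene, spec: SyntheticCohortSpec, rng: np.random.Generator
) -> tuple[Pieces, tuple[int, ...]]:
    """Tandem-duplicate [a' .. exon 2 .. b']; every middle intron then
    carries a b-arm upstream of an a-arm, with docker a in the left and
    docker b in the right flanking intron."""
    n = spec.n_duplications + 1
    block = [
        ("arm_a", gene.arm_a_prime),
        ("seq", gene.up_suffix),
        ("exon", gene.exon2),
        ("seq", gene.down_prefix),
        ("arm_b", gene.arm_b_prime),
    ]
    pieces: Pieces = [
        ("exon:1", gene.exon1),
        ("seq", gene.up_prefix),
        ("arm:a", gene.arm_a),
        ("seq", gene.up_loop),
    ]
    breakpoints = []
    off = sum(len(s) for _, s in pieces)
    for k in range(1, n + 1):
        breakpoints.append(off)
        for label, seq in block:
            mutated = _mutate(seq, spec.mutation_rate, rng)
            if label == "arm_a":
                pieces.append((f"arm:a_sel_{k}", mutated))
            elif label == "arm_b":
                pieces.append((f"arm:b_sel_{k}", mutated))
            elif label == "exon":
                pieces.append((f"exon:var_{k}", mutated))
            else:
                pieces.append(("seq", mutated))
            off += len(seq)
    pieces.append(("seq", gene.down_loop))
    pieces.append(("arm:b", gene.arm_b))
    pieces.append(("seq", gene.down_suffix))
    pieces.append(("exon:3", gene.exon3))
    return pieces, tuple(breakpoints)


def make_null_gene(
    spec: SyntheticCohortSpec, rng: np.random.Generator, n_exons: int = 4
) -> Pieces:
    """A gene with i.i.d. sequence, no duplication, no planted arms; its
    two transcripts share all exons, so it yields no MXE call."""
    pieces: Pieces = []
    for k in range(1, n_exons + 1):
        if k > 1:
            ilen = int(rng.integers(spec.intron_len - 150, spec.intron_len + 151))
            pieces.append(("seq", _random_seq(ilen, spec.gc, rng)))
        pieces.append((f"exon:{k}", _random_seq(spec.exon_len, spec.gc, rng)))
    return pieces


def _place_gene(
    gene_id: str,
    pieces: Pieces,
    breakpoints: tuple[int, ...],
    is_cluster: bool,
    spec: SyntheticCohortSpec,
    strand: str,
    rng: np.random.Generator,
) -> tuple[str, str, list[Transcript], GroundTruth]:
    """Place a gene-space piece list on its own contig; on the minus
    strand the contig holds the reverse complement and all features are
    coordinate-flipped."""
    gene_seq = "".join(seq for _, seq in pieces)
    spans = _spans(pieces)
    contig = (_random_seq(spec.flank, spec.gc, rng) + gene_seq
              + _random_seq(spec.flank, spec.gc, rng))
    clen = len(contig)

    def to_genomic(span: tuple[int, int]) -> GenomicInterval:
        s, e = span[0] + spec.flank, span[1] + spec.flank
        if strand == "-":
            s, e = clen - e, clen - s
        return GenomicInterval(gene_id, s, e, strand)

    if strand == "-":
        contig = reverse_complement(contig)

    exon_spans = {lbl.split(":", 1)[1]: sp for lbl, sp in spans.items()
                  if lbl.startswith("exon:")}
    arm_spans = {lbl.split(":", 1)[1]: sp for lbl, sp in spans.items()
                 if lbl.startswith("arm:")}

    transcripts = []
    if is_cluster:
        var_names = sorted(
            (n for n in exon_spans if n.startswith("var_")),
            key=lambda n: int(n.split("_")[1]),
        )
        constitutive = [nm for nm in ("0", "1") if nm in exon_spans]
        for k, vn in enumerate(var_names, 1):
            exons = [to_genomic(exon_spans[nm]) for nm in constitutive]
            exons += [to_genomic(exon_spans[vn]), to_genomic(exon_spans["3"])]
            exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
            transcripts.append(
                Transcript(id=f"{gene_id}_t{k}", gene_id=gene_id,
                           exons=tuple(exons))
            )
        variable = tuple(
            to_genomic(exon_spans[vn]) for vn in var_names
        )
    else:
        names = sorted(exon_spans, key=int)
        exons = [to_genomic(exon_spans[nm]) for nm in names]
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        for k in (1, 2):
            transcripts.append(
                Transcript(id=f"{gene_id}_t{k}", gene_id=gene_id,
                           exons=tuple(exons))
            )
        variable = ()

    dockers = {nm: to_genomic(sp) for nm, sp in arm_spans.items()
               if nm in ("a", "b")}
    selectors = {nm: to_genomic(sp) for nm, sp in arm_spans.items()
                 if nm not in ("a", "b")}
    truth = GroundTruth(
        gene_id=gene_id, is_cluster=is_cluster, mode=spec.mode,
        variable_exons=variable, docker_arms=dockers,
        selector_arms=selectors, breakpoints=breakpoints,
    )
    return gene_id, contig, transcripts, truth


def emit_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Generate the full cohort: positive genes first, then null genes,
    each on its own contig, with the conserved track marking planted arms
    (padded) plus random decoys."""
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    models = GeneModelSet()
    truths: dict[str, GroundTruth] = {}
    bed_pairs: list[tuple[str, int, int]] = []

    n_total = spec.n_positive + spec.n_null
    width = max(4, len(str(n_total)))
    dup = (apply_unidirectional_duplication
           if spec.mode == "unidirectional"
           else apply_bidirectional_duplication)

    for idx in range(n_total):
        gene_id = f"g{idx + 1:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        positive = idx < spec.n_positive
        if positive:
            factor = 1.0 + spec.age_scatter * float(rng.uniform(-1, 1))
            mu_g = min(1.0, max(0.0, spec.mutation_rate * factor))
            gspec = replace(spec, mutation_rate=mu_g)
            ancestral = make_ancestral_gene(gspec, rng)
            pieces, breakpoints = dup(ancestral, gspec, rng)
            # an ordinary constitutive exon and intron upstream of the
            # cluster, so the gene has introns outside the cluster
            ilen = int(rng.integers(spec.intron_len - 150,
                                    spec.intron_len + 151))
            head: Pieces = [
                ("exon:0", _random_seq(spec.exon_len, spec.gc, rng)),
                ("seq", _random_seq(ilen, spec.gc, rng)),
            ]
            shift = sum(len(s) for _, s in head)
            pieces = head + pieces
            breakpoints = tuple(b + shift for b in breakpoints)
        else:
            pieces, breakpoints = make_null_gene(spec, rng), ()
        gid, contig, transcripts, truth = _place_gene(
            gene_id, pieces, breakpoints, positive, spec, strand, rng
        )
        sequences[gid] = contig
        for t in transcripts:
            models.add(t)
        truths[gid] = truth
        for iv in list(truth.docker_arms.values()) + list(
            truth.selector_arms.values()
        ):
            bed_pairs.append(
                (iv.chrom, max(0, iv.start - spec.pad),
                 min(len(contig), iv.end + spec.pad))
            )

    # decoy conserved intervals in random introns across the cohort
    all_introns = []
    from .similarity import gene_introns

    for gid in sorted(models.genes):
        all_introns.extend(gene_introns(models.genes[gid]))
    n_decoys = max(1, round(spec.decoy_fraction * max(1, len(bed_pairs))))
    decoy_len = spec.arm_len + 2 * spec.pad
    for _ in range(n_decoys):
        iv = all_introns[int(rng.integers(len(all_introns)))]
        if len(iv) <= decoy_len:
            continue
        s = iv.start + int(rng.integers(len(iv) - decoy_len))
        bed_pairs.append((iv.chrom, s, s + decoy_len))

    return Cohort(
        spec=spec,
        models=models,
        store=SequenceStore(sequences),
        elems=IntervalSet.from_pairs(bed_pairs),
        truths=truths,
    )
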