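"""Splicing graph construction and mutually exclusive exon (MXE) calling.

The splicing graph is bipartite in edge kinds: nodes are splice sites and
edges are exons or introns of annotated transcripts. An MXE cluster is a
pair of nodes (u, v) joined by two or more vertex-independent paths that
consist of exactly three edges in the order intron-exon-intron; the number
of such paths equals the number of mutually exclusive exons n. The cluster
is materialized with its two constitutive flanking exons, the n variable
exons (2.1..2.n in pre-mRNA order) and the n+1 intervening introns, with
intron 0 ("left") closest to the 5' end of the pre-mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GeneModelSet, GenomicInterval, Transcript, derive_introns

Edge = tuple[int, int]  # genomic (start, end)


@dataclass
class SpliceGraph:
    """Bipartite splice-site graph of one gene (one chrom, one strand).

    Exon and intron edges are keyed by genomic (start, end); the value is
    the set of supporting transcript ids. Nodes are the distinct splice
    site positions, labelled by genomic side ('L' = genomic-left boundary
    of an exon / genomic-right end of an intron, 'R' = the converse).
    """

    gene_id: str
    chrom: str
    strand: str
    exon_edges: dict[Edge, set[str]] = field(default_factory=dict)
    intron_edges: dict[Edge, set[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[tuple[int, str]]:
        out: set[tuple[int, str]] = set()
        for s, e in self.exon_edges:
            out.add((s, "L"))
            out.add((e, "R"))
        for s, e in self.intron_edges:
            out.add((s, "R"))
            out.add((e, "L"))
        return out


@dataclass(frozen=True)
class MxeCluster:
    """A called MXE cluster in pre-mRNA orientation.

    ``variable_exons`` are ordered 5'->3' of the pre-mRNA; ``introns`` has
    n+1 entries, intron 0 = left flanking intron, intron n = right.
    """

    gene_id: str
    chrom: str
    strand: str
    flank_left_exon: GenomicInterval
    flank_right_exon: GenomicInterval
    variable_exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...]

    @property
    def n(self) -> int:
        return len(self.variable_exons)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("an MXE cluster needs at least two variable exons")
        if len(self.introns) != self.n + 1:
            raise ValueError("cluster must have n+1 introns")

    @property
    def left_intron(self) -> GenomicInterval:
        return self.introns[0]

    @property
    def right_intron(self) -> GenomicInterval:
        return self.introns[-1]

    @property
    def id(self) -> str:
        lo = min(e.start for e in self.variable_exons)
        hi = max(e.end for e in self.variable_exons)
        return f"{self.gene_id}:{self.chrom}:{lo}-{hi}"


def build_splice_graph(models: GeneModelSet, gene_id: str) -> SpliceGraph:
    """Graph of all exons and introns of one gene's transcripts.

    Shared coordinates merge into a single edge whose support is the union
    of transcript ids, so duplicated annotations leave the graph unchanged.
    """
    transcripts = models.genes[gene_id]
    g = SpliceGraph(
        gene_id=gene_id,
        chrom=transcripts[0].chrom,
        strand=transcripts[0].strand,
    )
    for t in transcripts:
        for e in t.exons:
            g.exon_edges.setdefault((e.start, e.end), set()).add(t.id)
        for i in derive_introns(t):
            g.intron_edges.setdefault((i.start, i.end), set()).add(t.id)
    return g


def _middle_exons(g: SpliceGraph, u: int, v: int) -> list[Edge]:
    """Exon edges (s, e) forming an intron-exon-intron path from splice
    site u (an exon end) to splice site v (an exon start), u < v."""
    out = []
    for (s, e) in g.exon_edges:
        if u < s < e < v and (u, s) in g.intron_edges and (e, v) in g.intron_edges:
            out.append((s, e))
    return sorted(out)


def _independent_groups(middles: list[Edge]) -> list[list[Edge]]:
    """Group middle exons that share a splice site (union-find on
    boundary positions); groups are pairwise vertex-independent."""
    parent: dict[Edge, Edge] = {m: m for m in middles}

    def find(x: Edge) -> Edge:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: Edge, b: Edge) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_site: dict[tuple[int, str], list[Edge]] = {}
    for s, e in middles:
        by_site.setdefault((s, "L"), []).append((s, e))
        by_site.setdefault((e, "R"), []).append((s, e))
    for members in by_site.values():
        for m in members[1:]:
            union(members[0], m)
    groups: dict[Edge, list[Edge]] = {}
    for m in middles:
        groups.setdefault(find(m), []).append(m)
    return [sorted(v) for v in sorted(groups.values())]


def count_independent_ie_paths(g: SpliceGraph, u: int, v: int) -> int:
    """Number of vertex-independent intron-exon-intron paths from u to v.

    Paths are internally disjoint iff their middle exons share no splice
    site, so the maximum internally-disjoint set has one path per group of
    splice-site-sharing middle exons.
    """
    return len(_independent_groups(_middle_exons(g, u, v)))


def _shortest(edges: list[Edge]) -> Edge:
    return min(edges, key=lambda se: (se[1] - se[0], se))


def find_mxe_clusters(g: SpliceGraph, strict: bool = False) -> list[MxeCluster]:
    """All MXE clusters of the gene's splicing graph.

    Candidate node pairs are (intron start, intron end) pairs with >= 2
    vertex-independent intron-exon-intron paths. A candidate nested inside
    an already-reported cluster with the identical variable-exon set is
    suppressed. When several exons share both splice sites the shortest
    represents its independence group; flanking exons are likewise the
    shortest exon edge incident to u (upstream) and v (downstream).

    With ``strict=True``, clusters in which any single transcript contains
    two variable exons are dropped (the default graph-only definition does
    not apply this filter).
    """
    donors = sorted({s for s, _ in g.intron_edges})
    acceptors = sorted({e for _, e in g.intron_edges})
    candidates = []
    for u in donors:
        for v in acceptors:
            if v <= u:
                continue
            groups = _independent_groups(_middle_exons(g, u, v))
            if len(groups) < 2:
                continue
            variable = tuple(sorted(_shortest(grp) for grp in groups))
            candidates.append((u, v, variable))

    # widest span first, so nested same-exon-set candidates are suppressed
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[1]))
    kept: list[tuple[int, int, tuple[Edge, ...]]] = []
    for u, v, variable in candidates:
        nested = any(
            set(variable) == set(kv) and ku <= u and v <= kvv
            for ku, kvv, kv in kept
        )
        if not nested:
            kept.append((u, v, variable))

    clusters = []
    for u, v, variable in sorted(kept):
        left_candidates = [(s, e) for (s, e) in g.exon_edges if e == u]
        right_candidates = [(s, e) for (s, e) in g.exon_edges if s == v]
        if not left_candidates or not right_candidates:
            continue
        flank_left = _shortest(left_candidates)
        flank_right = _shortest(right_candidates)
        gaps = [(u, variable[0][0])]
        for a, b in zip(variable, variable[1:]):
            gaps.append((a[1], b[0]))
        gaps.append((variable[-1][1], v))
        if any(s >= e for s, e in gaps):
            # overlapping variable exons leave no genomic gap intron;
            # such candidates cannot be materialized in Fig-style geometry
            continue

        mk = lambda se: GenomicInterval(g.chrom, se[0], se[1], g.strand)
        exons_pre = [mk(se) for se in variable]
        introns_pre = [mk(sg) for sg in gaps]
        fl, fr = mk(flank_left), mk(flank_right)
        if g.strand == "-":
            exons_pre.reverse()
            introns_pre.reverse()
            fl, fr = fr, fl
        cluster = MxeCluster(
            gene_id=g.gene_id,
            chrom=g.chrom,
            strand=g.strand,
            flank_left_exon=fl,
            flank_right_exon=fr,
            variable_exons=tuple(exons_pre),
            introns=tuple(introns_pre),
        )
        if strict and _transcript_spans_two(g, cluster):
            continue
        clusters.append(cluster)
    return clusters


def _transcript_spans_two(g: SpliceGraph, cluster: MxeCluster) -> bool:
    var = {(e.start, e.end) for e in cluster.variable_exons}
    support: dict[str, int] = {}
    for edge, tids in g.exon_edges.items():
        if edge in var:
            for tid in tids:
                support[tid] = support.get(tid, 0) + 1
    return any(c >= 2 for c in support.values())


def find_all_clusters(models: GeneModelSet, strict: bool = False) -> list[MxeCluster]:
    """MXE clusters across all genes, in deterministic gene-id order."""
    out = []
    for gene_id in sorted(models.genes):
        g = build_splice_graph(models, gene_id)
        out.extend(find_mxe_clusters(g, strict=strict))
    return out
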