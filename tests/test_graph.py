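import numpy as np
import pytest

from mxefold.genome import GeneModelSet, GenomicInterval, Transcript
from mxefold.graph import (
    build_splice_graph,
    count_independent_ie_paths,
    find_all_clusters,
    find_mxe_clusters,
)

from conftest import random_toy_models
from oracles import independent_ie_paths_bruteforce


def test_two_transcript_mxe_graph_shape(toy_models):
    g = build_splice_graph(toy_models, "gA")
    assert len(g.exon_edges) == 4
    assert len(g.intron_edges) == 4
    assert len(g.nodes) == 8
    assert count_independent_ie_paths(g, 200, 700) == 2


def test_single_transcript_edge_counts():
    mk = lambda s, e: GenomicInterval("c", s, e)
    models = GeneModelSet()
    models.add(Transcript("t", "g", (mk(0, 10), mk(20, 30), mk(40, 50))))
    g = build_splice_graph(models, "g")
    assert len(g.exon_edges) == 3
    assert len(g.intron_edges) == 2


def test_duplicate_transcript_is_idempotent(toy_models):
    before = build_splice_graph(toy_models, "gA")
    dup = Transcript("t1_copy", "gA", toy_models.genes["gA"][0].exons)
    toy_models.add(dup)
    after = build_splice_graph(toy_models, "gA")
    assert set(after.exon_edges) == set(before.exon_edges)
    assert set(after.intron_edges) == set(before.intron_edges)
    assert "t1_copy" in after.exon_edges[(100, 200)]


def test_cassette_exon_is_not_an_mxe():
    # inclusion and skip isoform: the skip path is one intron edge, not
    # an intron-exon-intron path, so only one independent path exists
    mk = lambda s, e: GenomicInterval("c", s, e)
    models = GeneModelSet()
    models.add(Transcript("inc", "g", (mk(0, 10), mk(20, 30), mk(40, 50))))
    models.add(Transcript("skp", "g", (mk(0, 10), mk(40, 50))))
    g = build_splice_graph(models, "g")
    assert count_independent_ie_paths(g, 10, 40) == 1
    assert find_mxe_clusters(g) == []


def test_random_graphs_match_bruteforce():
    rng = np.random.default_rng(202)
    for _ in range(30):
        models = random_toy_models(rng)
        g = build_splice_graph(models, "g")
        donors = {s for s, _ in g.intron_edges}
        acceptors = {e for _, e in g.intron_edges}
        for u in donors:
            for v in acceptors:
                if v <= u:
                    continue
                got = count_independent_ie_paths(g, u, v)
                want = independent_ie_paths_bruteforce(
                    set(g.exon_edges), set(g.intron_edges), u, v
                )
                assert got == want, (u, v, sorted(g.exon_edges),
                                     sorted(g.intron_edges))


def test_cluster_structure_and_orientation(uni_cohort):
    clusters = find_all_clusters(uni_cohort.models)
    truths = uni_cohort.truths
    assert {c.gene_id for c in clusters} == {
        g for g, t in truths.items() if t.is_cluster
    }
    for c in clusters:
        assert c.n == len(c.variable_exons) == len(c.introns) - 1
        truth = truths[c.gene_id]
        assert {(e.start, e.end) for e in c.variable_exons} == {
            (e.start, e.end) for e in truth.variable_exons
        }
        # left intron is 5'-most in the pre-mRNA regardless of strand
        if c.strand == "+":
            assert c.left_intron.start < c.right_intron.start
        else:
            assert c.left_intron.start > c.right_intron.start
        # intron i sits between variable exons i and i+1 in pre-mRNA order
        for i, e in enumerate(c.variable_exons):
            a, b = c.introns[i], c.introns[i + 1]
            if c.strand == "+":
                assert a.end == e.start and e.end == b.start
            else:
                assert a.start == e.end and e.start == b.end


def test_determinism_under_transcript_reordering(uni_cohort):
    models = uni_cohort.models
    shuffled = GeneModelSet()
    for gid in sorted(models.genes, reverse=True):
        for t in reversed(models.genes[gid]):
            shuffled.add(t)
    a = find_all_clusters(models)
    b = find_all_clusters(shuffled)
    assert [(c.gene_id, c.variable_exons, c.introns) for c in a] == [
        (c.gene_id, c.variable_exons, c.introns) for c in b
    ]


def test_two_disjoint_clusters_in_one_gene():
    mk = lambda s, e: GenomicInterval("c", s, e)
    models = GeneModelSet()
    # cluster 1 between exons (0,10) and (100,110); cluster 2 between
    # (100,110) and (200,210)
    models.add(Transcript("t1", "g", (mk(0, 10), mk(20, 30), mk(100, 110),
                                      mk(120, 130), mk(200, 210))))
    models.add(Transcript("t2", "g", (mk(0, 10), mk(50, 60), mk(100, 110),
                                      mk(150, 160), mk(200, 210))))
    g = build_splice_graph(models, "g")
    clusters = find_mxe_clusters(g)
    spans = sorted((c.flank_left_exon.end, c.flank_right_exon.start)
                   for c in clusters)
    assert spans == [(10, 100), (110, 200)]


def test_strict_flag_filters_co_occurring_exons():
    mk = lambda s, e: GenomicInterval("c", s, e)
    models = GeneModelSet()
    models.add(Transcript("t1", "g", (mk(0, 10), mk(20, 30), mk(100, 110))))
    models.add(Transcript("t2", "g", (mk(0, 10), mk(50, 60), mk(100, 110))))
    # one isoform contains both middle exons: still a cluster by the
    # graph definition, removed under strict
    models.add(Transcript("t3", "g", (mk(0, 10), mk(20, 30), mk(50, 60),
                                      mk(100, 110))))
    g = build_splice_graph(models, "g")
    assert len(find_mxe_clusters(g)) == 1
    assert find_mxe_clusters(g, strict=True) == []
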