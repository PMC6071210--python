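import numpy as np
import pytest

from mxefold.duplex import (
    PairClass,
    ScanRow,
    HybridizationResult,
    cluster_hybridization_scan,
    conserved_concat,
    ddg,
    docker_site_map,
    duplex_mfe,
)
from mxefold.energies import EnergyParams
from mxefold.genome import GenomicInterval, IntervalSet, SequenceStore
from mxefold.genome import reverse_complement
from mxefold.graph import find_all_clusters

from oracles import duplex_bruteforce

P = EnergyParams()


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_perfect_helix_closed_form():
    dG, sx, sy = duplex_mfe("GGGGGG", "CCCCCC", P)
    expected = 5 * P.stack_energy("GG", "CC") + P.init
    assert dG == pytest.approx(expected)
    assert sx == (0, 6) and sy == (0, 6)


def test_no_structure_cases():
    assert duplex_mfe("AAAA", "AAAA", P) == (0.0, None, None)
    # a single G.C pair is a lonely pair, suppressed under noLP
    assert duplex_mfe("GAAAC", "GAAAC", P) == (0.0, None, None)


def test_lonely_pair_allowed_without_nolp():
    p = EnergyParams(no_lonely_pairs=False)
    dG, sx, sy = duplex_mfe("GAAAC", "GAAAC", p)
    assert dG == pytest.approx(p.init)  # one pair, no stack
    assert sx is not None


def test_dp_matches_bruteforce_random_8mers():
    rng = np.random.default_rng(31)
    for _ in range(50):
        x, y = random_seq(rng, 8), random_seq(rng, 8)
        got = duplex_mfe(x, y, P)[0]
        want = duplex_bruteforce(x, y, P)
        if want is None:
            assert got == 0.0
        else:
            assert got == pytest.approx(want), (x, y)


def test_symmetry_under_swap():
    # the optimal energy is symmetric; sites may differ among co-optimal
    # structures because ties are broken toward x's 5' end
    rng = np.random.default_rng(5)
    for _ in range(20):
        x, y = random_seq(rng, 12), random_seq(rng, 12)
        dxy, sx, sy = duplex_mfe(x, y, P)
        dyx, tx, ty = duplex_mfe(y, x, P)
        assert dxy == pytest.approx(dyx)
        assert (sx is None) == (tx is None)


def test_nonpairing_flank_leaves_score_unchanged():
    x, y = "GGCGGC", "GCCGCC"
    base = duplex_mfe(x, y, P)[0]
    assert duplex_mfe("AAAA" + x + "AAAA", y, P)[0] == pytest.approx(base)
    assert duplex_mfe(x, "AAAA" + y + "AAAA", P)[0] == pytest.approx(base)


def test_extending_helix_never_raises_energy():
    prev = float("inf")
    for k in range(2, 12):
        dG = duplex_mfe("G" * k, "C" * k, P)[0]
        assert dG <= prev
        prev = dG


def test_conserved_concat_plus_and_minus():
    store = SequenceStore({"c": "AAACCCGGGTTTAAACCCGG"})
    elems = IntervalSet.from_pairs([("c", 3, 6), ("c", 9, 12)])
    plus = conserved_concat(GenomicInterval("c", 0, 20, "+"), elems, store)
    assert plus.sequence == "CCC" + "TTT"
    assert [(o, (iv.start, iv.end)) for o, iv in plus.segment_map] == [
        (0, (3, 6)), (3, (9, 12))
    ]
    minus = conserved_concat(GenomicInterval("c", 0, 20, "-"), elems, store)
    # transcript order: genomically last segment first, each revcomped
    assert minus.sequence == reverse_complement("TTT") + reverse_complement("CCC")
    # back-mapping returns intervals inside the source segments
    for iv in minus.map_back(0, 5):
        assert 3 <= iv.start and iv.end <= 12


def test_conserved_concat_empty():
    store = SequenceStore({"c": "ACGTACGT"})
    elems = IntervalSet.from_pairs([("c", 100, 200)])
    cc = conserved_concat(GenomicInterval("c", 0, 8), elems, store)
    assert cc.sequence == "" and cc.segment_map == []


def test_ddg_homopolymer_shuffle_is_identity():
    rng = np.random.default_rng(1)
    res = ddg("A" * 30, "A" * 30, control="shuffle", params=P, rng=rng)
    assert res.ddG == 0.0 and not res.discarded


def test_ddg_discard_rule():
    # strong true duplex vs a non-pairing length-matched control pool
    rng = np.random.default_rng(2)
    pool = ["A" * k for k in range(20, 60)]
    res = ddg("G" * 30, "C" * 30, control="length_matched", params=P,
              rng=rng, pool=pool, threshold=30.0)
    assert res.dG0 == 0.0
    assert abs(res.ddG) > 30
    assert res.discarded


def test_planted_complementary_arms_give_negative_ddg():
    rng = np.random.default_rng(8)
    hits = 0
    reps = 100
    for _ in range(reps):
        arm = random_seq(rng, 20)
        x = random_seq(rng, 140) + arm + random_seq(rng, 140)
        y = random_seq(rng, 140) + reverse_complement(arm) + random_seq(rng, 140)
        res = ddg(x, y, control="shuffle", params=P,
                  rng=rng, threshold=1e9)
        if res.ddG < 0:
            hits += 1
    assert hits >= 0.95 * reps


def test_cluster_scan_row_counts(uni_cohort):
    clusters = find_all_clusters(uni_cohort.models)
    c = clusters[0]
    assert c.n == 3
    rows = cluster_hybridization_scan(
        c, uni_cohort.elems, uni_cohort.store, params=P,
        rng=np.random.default_rng(3),
    )
    by_class = {}
    for r in rows:
        by_class.setdefault(r.pair_class, 0)
        by_class[r.pair_class] += 1
    # n=3: internal introns 1..2 -> 2 L_to_i, 1 i_to_j; the right intron
    # of a unidirectional cluster has conserved decoys only sometimes
    assert by_class[PairClass.L_to_i] == 2
    assert by_class[PairClass.i_to_j] == 1
    for r in rows:
        for iv in r.sites_x_genomic:
            src = c.introns[r.i]
            assert src.start <= iv.start and iv.end <= src.end


def test_docker_site_map_merging():
    mk = lambda s, e: GenomicInterval("c", s, e, "+")
    res = HybridizationResult(-5, -1, -4, (0, 10), (0, 10), False)
    rows = [
        ScanRow("cl", "g", PairClass.L_to_i, 0, 1, res, [mk(10, 30)], []),
        ScanRow("cl", "g", PairClass.L_to_i, 0, 2, res, [mk(25, 45)], []),
    ]
    records = docker_site_map(rows)
    assert len(records) == 1
    chrom, s, e, name, score, strand = records[0]
    assert (s, e, score) == (10, 45, 2)

    # non-overlapping partner sites stay separate with score 1
    rows[1] = ScanRow("cl", "g", PairClass.L_to_i, 0, 2, res, [mk(60, 70)], [])
    records = docker_site_map(rows)
    assert [(r[1], r[2], r[4]) for r in records] == [(10, 30, 1), (60, 70, 1)]


def test_external_engine_adapter_parses_rnaduplex():
    from mxefold.duplex import external_duplex_mfe

    dG, sx, sy = external_duplex_mfe("GGGGGGGG", "CCCCCCCC")
    assert dG < -5
    assert sx is not None and 0 <= sx[0] < sx[1] <= 8
    assert sy is not None and 0 <= sy[0] < sy[1] <= 8
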