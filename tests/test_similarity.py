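import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mxefold.graph import find_all_clusters
from mxefold.similarity import (
    AlignScoring,
    build_intron_pool,
    consecutive_pair_table,
    conservation_table,
    length_matched_control,
    local_alignment_score,
    random_intron_same_gene,
    similarity,
)
from mxefold.simulate import SyntheticCohortSpec, emit_cohort

from oracles import sw_bruteforce

SC = AlignScoring()
DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


def test_alignment_score_simple_cases():
    assert local_alignment_score("ACGT", "ACGT", SC) == 4.0
    assert local_alignment_score("AAAA", "CCCC", SC) == 0.0


def test_alignment_score_matches_bruteforce_8mers():
    # frozen from the exhaustive path enumerator
    assert sw_bruteforce("ACGTACGT", "ACGTTTTT", SC) == pytest.approx(4.4)
    assert local_alignment_score("ACGTACGT", "ACGTTTTT", SC) == pytest.approx(4.4)


def test_alignment_matches_bruteforce_random_short():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    for _ in range(60):
        x = "".join(rng.choice(bases, size=rng.integers(1, 7)))
        y = "".join(rng.choice(bases, size=rng.integers(1, 7)))
        assert local_alignment_score(x, y, SC) == pytest.approx(
            sw_bruteforce(x, y, SC)
        ), (x, y)


def test_alignment_rejects_invalid_alphabet():
    with pytest.raises(ValueError):
        local_alignment_score("ACGN", "ACGT", SC)
    with pytest.raises(ValueError):
        similarity("", "ACGT", SC)


@settings(max_examples=60, deadline=None)
@given(DNA, DNA)
def test_sigma_bounds_and_symmetry(x, y):
    a = similarity(x, y, SC)
    b = similarity(y, x, SC)
    assert 0.0 <= a.sigma <= 1.0
    assert a.sigma == pytest.approx(b.sigma)


@settings(max_examples=30, deadline=None)
@given(DNA)
def test_sigma_identity(x):
    assert similarity(x, x, SC).sigma == pytest.approx(1.0)


def test_sigma_derived_example():
    # s_xx = 8 for the 8-mer, s_xy frozen from the brute-force oracle
    res = similarity("ACGTACGT", "ACGTTTTT", SC)
    assert res.s_xx == 8.0
    assert res.sigma == pytest.approx(4.4 / 8.0)


class TestLengthMatchedControl:
    def test_clamping_and_self_exclusion(self):
        pool = ["A", "AC", "ACG"]
        rng = np.random.default_rng(0)
        draws = {length_matched_control(0, pool, rng) for _ in range(200)}
        assert draws <= {"AC", "ACG"}

    def test_identical_length_pool_matches_query_length(self):
        pool = ["AAAA", "CCCC", "GGGG", "TTTT"]
        rng = np.random.default_rng(1)
        for i in range(4):
            assert len(length_matched_control(i, pool, rng)) == 4

    def test_pool_of_one_errors(self):
        with pytest.raises(ValueError):
            length_matched_control(0, ["AAAA"], np.random.default_rng(0))

    def test_offset_distribution_matches_direct_simulation(self):
        # rank-offset rule simulated independently
        pool = ["A" * (5 + k) for k in range(200)]
        rank = 100
        rng = np.random.default_rng(5)
        got = np.array(
            [len(length_matched_control(rank, pool, rng)) - len(pool[rank])
             for _ in range(10_000)]
        )
        rng2 = np.random.default_rng(17)
        offsets = []
        while len(offsets) < 10_000:
            d = int(rng2.integers(-10, 11))
            if d:
                offsets.append(d)
        want = np.array(offsets)
        # both are uniform on {-10..10}\{0}: compare histograms
        gh = np.bincount(got + 10, minlength=21)
        wh = np.bincount(want + 10, minlength=21)
        assert sps.chisquare(gh[gh > 0], wh[wh > 0]).pvalue > 0.001


class TestRandomIntronSameGene:
    def test_excludes_cluster_introns_and_is_deterministic(self, uni_cohort):
        clusters = find_all_clusters(uni_cohort.models)
        c = clusters[0]
        transcripts = uni_cohort.models.genes[c.gene_id]
        excluded = {(iv.start, iv.end) for iv in c.introns}
        draws = [
            random_intron_same_gene(c, transcripts, np.random.default_rng(9))
            for _ in range(5)
        ]
        assert len({(d.start, d.end) for d in draws}) == 1  # fixed seed
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = random_intron_same_gene(c, transcripts, rng)
            assert (d.start, d.end) not in excluded

    def test_uniform_over_eligible(self, uni_cohort):
        clusters = find_all_clusters(uni_cohort.models)
        c = clusters[0]
        transcripts = uni_cohort.models.genes[c.gene_id]
        rng = np.random.default_rng(23)
        counts = {}
        for _ in range(10_000):
            d = random_intron_same_gene(c, transcripts, rng)
            counts[(d.start, d.end)] = counts.get((d.start, d.end), 0) + 1
        freqs = np.array(list(counts.values()))
        assert sps.chisquare(freqs).pvalue > 0.01


def test_consecutive_pair_table_shape_and_identity():
    cohort = emit_cohort(
        SyntheticCohortSpec(n_positive=3, n_null=3, mutation_rate=0.0,
                            seed=42)
    )
    clusters = find_all_clusters(cohort.models)
    pool = build_intron_pool(cohort.models, cohort.store)
    table = consecutive_pair_table(
        clusters, cohort.store, pool, np.random.default_rng(1)
    )
    # n = 3 variable exons -> 3 consecutive intron pairs per cluster
    assert (table.groupby("cluster_id").size() == 3).all()
    # with zero mutations the duplicated middle-intron pairs share most
    # of their sequence; pairs of identical copies score sigma == 1
    middle = table[table.i == 1]
    assert (middle.sigma_introns > 0.9).all()
    assert (table.delta_sigma > 0).all()


def test_delta_sigma_positive_on_duplicated_cohort(uni_cohort):
    clusters = find_all_clusters(uni_cohort.models)
    pool = build_intron_pool(uni_cohort.models, uni_cohort.store)
    table = consecutive_pair_table(
        clusters, uni_cohort.store, pool, np.random.default_rng(2)
    )
    assert table.delta_sigma.median() > 0


def test_conservation_contrast(uni_cohort):
    clusters = find_all_clusters(uni_cohort.models)
    table = conservation_table(
        clusters, uni_cohort.models, uni_cohort.elems,
        np.random.default_rng(4)
    )
    mxe = table[table.role == "mxe_flanking"].fraction
    ctrl = table[table.role == "control"].fraction
    # planted arms make cluster introns more covered on average
    assert mxe.mean() > ctrl.mean()
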