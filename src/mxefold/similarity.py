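"""Conservation fractions and normalized local-alignment similarity.

Two questions are asked of every MXE cluster. First, are its flanking
introns more evolutionarily conserved than a randomly chosen intron of
the same gene (conservation fraction against a conserved-element mask)?
Second, do consecutive introns of the cluster retain sequence similarity
from the tandem duplication that created it? Similarity is a local
(Smith-Waterman) alignment score normalized by the best self-alignment,

    sigma(x, y) = s(x, y) / max(s(x, x), s(y, y)),

which lies in [0, 1] and equals 1 for identical sequences. Each observed
pair is compared against a control pair drawn from a length-matched pool
(sequences sorted by length; rank perturbed by a random offset of at most
+/-10), giving delta_sigma = sigma - sigma0.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .genome import (
    GeneModelSet,
    GenomicInterval,
    IntervalSet,
    SequenceStore,
    Transcript,
    coverage_fraction,
    derive_introns,
    extract_sequence,
)
from .graph import MxeCluster

log = logging.getLogger(__name__)

MAX_ALIGN_LEN = 10_000
_VALID = set("ACGT")


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scoring; a gap of length k costs
    |gap_open| + |gap_extend| * (k - 1)."""

    match: float = 1.0
    mismatch: float = -0.2
    gap_open: float = -1.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner(mode="local")
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


@dataclass
class SimilarityResult:
    s_xy: float
    s_xx: float
    s_yy: float
    sigma: float
    delta_sigma: float | None = None


def _check_seq(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{name} contains invalid characters {sorted(bad)}")


def local_alignment_score(x: str, y: str, sc: AlignScoring | None = None) -> float:
    """Best local alignment score of x and y (empty alignment scores 0)."""
    sc = sc or AlignScoring()
    _check_seq(x, "x")
    _check_seq(y, "y")
    return float(sc.aligner().score(x, y))


def similarity(x: str, y: str, sc: AlignScoring | None = None) -> SimilarityResult:
    """Normalized similarity sigma(x, y) = s(x,y) / max(s(x,x), s(y,y))."""
    sc = sc or AlignScoring()
    aligner = sc.aligner()
    _check_seq(x, "x")
    _check_seq(y, "y")
    s_xy = float(aligner.score(x, y))
    s_xx = float(aligner.score(x, x))
    s_yy = float(aligner.score(y, y))
    return SimilarityResult(
        s_xy=s_xy, s_xx=s_xx, s_yy=s_yy, sigma=s_xy / max(s_xx, s_yy)
    )


def length_matched_control(
    seq_index: int,
    pool: list[str],
    rng: np.random.Generator,
    max_offset: int = 10,
) -> str:
    """A control sequence from a length-sorted pool near a given rank.

    The rank is perturbed by a uniform non-zero offset in
    [-max_offset, +max_offset], clamped to the pool bounds; the query
    entry itself is never returned.
    """
    if len(pool) < 2:
        raise ValueError("control pool must contain at least two sequences")
    delta = 0
    while delta == 0:
        delta = int(rng.integers(-max_offset, max_offset + 1))
    idx = min(max(seq_index + delta, 0), len(pool) - 1)
    if idx == seq_index:
        idx = seq_index + 1 if seq_index + 1 < len(pool) else seq_index - 1
    return pool[idx]


def control_for_sequence(
    seq: str, pool: list[str], rng: np.random.Generator, max_offset: int = 10
) -> str:
    """Length-matched control for an arbitrary sequence: its rank is
    where the sequence would sit in the length-sorted pool."""
    lengths = [len(s) for s in pool]
    rank = min(bisect_left(lengths, len(seq)), len(pool) - 1)
    return length_matched_control(rank, pool, rng, max_offset=max_offset)


def gene_introns(transcripts: list[Transcript]) -> list[GenomicInterval]:
    """Distinct annotated introns of a gene, sorted genomically."""
    seen = {}
    for t in transcripts:
        for iv in derive_introns(t):
            seen[(iv.start, iv.end)] = iv
    return [seen[k] for k in sorted(seen)]


def random_intron_same_gene(
    cluster: MxeCluster,
    transcripts: list[Transcript],
    rng: np.random.Generator,
) -> GenomicInterval | None:
    """Uniformly chosen annotated intron of the gene outside the
    cluster's intron set; None (logged) when no intron is eligible."""
    excluded = {(iv.start, iv.end) for iv in cluster.introns}
    eligible = [
        iv for iv in gene_introns(transcripts)
        if (iv.start, iv.end) not in excluded
    ]
    if not eligible:
        log.debug("cluster %s: no eligible control intron", cluster.id)
        return None
    return eligible[int(rng.integers(len(eligible)))]


def conservation_table(
    clusters: list[MxeCluster],
    models: GeneModelSet,
    elems: IntervalSet,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Conserved-base fractions of MXE-flanking introns and of random
    same-gene control introns, one control draw per cluster intron."""
    rows = []
    for cluster in clusters:
        transcripts = models.genes[cluster.gene_id]
        for k, iv in enumerate(cluster.introns):
            rows.append(
                dict(
                    cluster_id=cluster.id, gene_id=cluster.gene_id,
                    intron_index=k, role="mxe_flanking",
                    chrom=iv.chrom, start=iv.start, end=iv.end,
                    fraction=coverage_fraction(iv, elems),
                )
            )
            ctrl = random_intron_same_gene(cluster, transcripts, rng)
            if ctrl is not None:
                rows.append(
                    dict(
                        cluster_id=cluster.id, gene_id=cluster.gene_id,
                        intron_index=k, role="control",
                        chrom=ctrl.chrom, start=ctrl.start, end=ctrl.end,
                        fraction=coverage_fraction(ctrl, elems),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "gene_id", "intron_index", "role",
                 "chrom", "start", "end", "fraction"],
    )


def build_intron_pool(
    models: GeneModelSet, store: SequenceStore, max_len: int = MAX_ALIGN_LEN
) -> list[str]:
    """Genome-wide pool of distinct intron sequences sorted by length."""
    seqs = []
    for gene_id in sorted(models.genes):
        for iv in gene_introns(models.genes[gene_id]):
            if len(iv) <= max_len:
                seq = extract_sequence(iv, store)
                if not set(seq) - _VALID:
                    seqs.append(seq)
    seqs.sort(key=len)
    return seqs


def consecutive_pair_table(
    clusters: list[MxeCluster],
    store: SequenceStore,
    pool: list[str],
    rng: np.random.Generator,
    sc: AlignScoring | None = None,
    max_len: int = MAX_ALIGN_LEN,
    control_both: bool = True,
    exclude_genes: set[str] | None = None,
) -> pd.DataFrame:
    """One row per consecutive intron pair (i, i+1) of every cluster.

    Columns hold sigma of the intron pair, sigma0 of a length-matched
    control pair (both members re-drawn by default; with
    ``control_both=False`` only the second), delta_sigma, and sigma of
    the adjacent variable exons i and i+1. Pairs with a sequence longer
    than ``max_len`` are omitted.
    """
    sc = sc or AlignScoring()
    rows = []
    for cluster in clusters:
        if exclude_genes and cluster.gene_id in exclude_genes:
            continue
        intron_seqs = [extract_sequence(iv, store) for iv in cluster.introns]
        exon_seqs = [extract_sequence(e, store) for e in cluster.variable_exons]
        for i in range(cluster.n):
            x, y = intron_seqs[i], intron_seqs[i + 1]
            if len(x) > max_len or len(y) > max_len:
                log.debug("%s pair (%d,%d): length cap, omitted",
                          cluster.id, i, i + 1)
                continue
            if set(x) - _VALID or set(y) - _VALID:
                log.debug("%s pair (%d,%d): non-ACGT, omitted",
                          cluster.id, i, i + 1)
                continue
            sig = similarity(x, y, sc).sigma
            cx = control_for_sequence(x, pool, rng) if control_both else x
            cy = control_for_sequence(y, pool, rng)
            sig0 = similarity(cx, cy, sc).sigma
            if i >= 1:
                # introns i, i+1 correspond to variable exons 2.i, 2.(i+1)
                ex, ey = exon_seqs[i - 1], exon_seqs[i]
                sigma_exons = similarity(ex, ey, sc).sigma if not (
                    set(ex) - _VALID or set(ey) - _VALID
                ) else np.nan
            else:
                # intron pair (0, 1) has no consecutive-exon counterpart
                sigma_exons = np.nan
            rows.append(
                dict(
                    cluster_id=cluster.id, gene_id=cluster.gene_id, i=i,
                    sigma_introns=sig, sigma0=sig0,
                    delta_sigma=sig - sig0, sigma_exons=sigma_exons,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "gene_id", "i", "sigma_introns", "sigma0",
                 "delta_sigma", "sigma_exons"],
    )
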