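"""Intermolecular duplex MFE, ΔΔG against controls, and docker-site maps.

The built-in engine is a nearest-neighbor duplex dynamic program over all
intermolecular structures made of stacked Watson-Crick/G-U pairs separated
by interior/bulge loops (opening penalty plus linear per-base penalty,
capped total size), plus
one initiation penalty; lonely (single-pair) helices are suppressed by
default. Intramolecular structure (accessibility) is not modelled, so
absolute ΔG values are engine-specific; the statistic of record is
ΔΔG = ΔG(true pair) − ΔG(control pair), with records discarded when
|ΔΔG| exceeds a threshold (default 30 kcal/mol).

To focus on the evolutionarily constrained part of an intron, sequences
can be reduced to the concatenation of their conserved elements before
folding, with a segment map for projecting duplex sites back to genomic
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from ._kernels import INF, duplex_dp
from .energies import EnergyParams
from .genome import GenomicInterval, IntervalSet, SequenceStore, extract_sequence
from .graph import MxeCluster
from .shuffle import ShuffleConfig, encode, shuffle

log = logging.getLogger(__name__)

_EPS = 1e-7


class PairClass(str, Enum):
    """Which introns of a cluster a hybridized pair came from."""

    L_to_i = "L_to_i"  # left flanking intron vs. an internal intron
    i_to_j = "i_to_j"  # two internal introns
    j_to_R = "j_to_R"  # an internal intron vs. the right flanking intron


@dataclass
class HybridizationResult:
    dG: float
    dG0: float
    ddG: float
    site_x: tuple[int, int] | None
    site_y: tuple[int, int] | None
    discarded: bool


@dataclass
class ConservedConcat:
    """Concatenated conserved parts of an interval, 5'->3' of the
    pre-mRNA, with a map back to the source genomic segments."""

    sequence: str
    segment_map: list[tuple[int, GenomicInterval]]

    def map_back(self, start: int, end: int) -> list[GenomicInterval]:
        """Genomic intervals underlying concat positions [start, end)."""
        out = []
        for off, iv in self.segment_map:
            seg_len = len(iv)
            lo = max(start, off)
            hi = min(end, off + seg_len)
            if lo >= hi:
                continue
            if iv.strand == "+":
                out.append(
                    GenomicInterval(iv.chrom, iv.start + (lo - off),
                                    iv.start + (hi - off), iv.strand)
                )
            else:
                # concat offset 0 is the genomic end on the minus strand
                out.append(
                    GenomicInterval(iv.chrom, iv.end - (hi - off),
                                    iv.end - (lo - off), iv.strand)
                )
        return out


def duplex_mfe(
    x: str, y: str, params: EnergyParams | None = None
) -> tuple[float, tuple[int, int] | None, tuple[int, int] | None]:
    """MFE duplex of x with y and its site on each sequence.

    Returns (dG, site_x, site_y); sites are 0-based half-open intervals on
    the input sequences (both 5'->3'). When no legal structure exists the
    result is (0.0, None, None). Ties are broken toward the 5'-most
    closing pair on x, then on y.
    """
    params = params or EnergyParams()
    xa, ya = encode(x), encode(y)
    if xa.size == 0 or ya.size == 0:
        return 0.0, None, None
    P1, P2 = duplex_dp(
        xa, ya, params._pairable, params._stack,
        params.loop_open, params.loop_per_base, params.init,
        params.max_loop, params.no_lonely_pairs,
    )
    final = P2 if params.no_lonely_pairs else np.minimum(P1, P2)
    best = final.min()
    if best >= INF / 2:
        return 0.0, None, None
    cells = np.argwhere(final <= best + _EPS)
    i, j = min(map(tuple, cells))
    pairs = _traceback(xa, ya, P1, P2, int(i), int(j), params)
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    return float(best), (min(xs), max(xs) + 1), (min(ys), max(ys) + 1)


def _traceback(xa, ya, P1, P2, i, j, params):
    """Reconstruct the pair list of the optimal duplex ending at (i, j)."""
    pairs = [(i, j)]
    # was the closing pair stacked or a helix start?
    in_p2 = params.no_lonely_pairs or P2[i, j] <= P1[i, j] + _EPS
    while True:
        if in_p2:
            base = params._stack[xa[i - 1], ya[j + 1], xa[i], ya[j]]
            rem = P2[i, j] - base
            i, j = i - 1, j + 1
            pairs.append((i, j))
            if abs(rem - P2[i, j]) <= _EPS:
                in_p2 = True
            elif abs(rem - P1[i, j]) <= _EPS:
                in_p2 = False
            else:  # pragma: no cover - defensive
                raise AssertionError("duplex traceback lost (stack)")
        else:
            target = P1[i, j]
            if abs(target - params.init) <= _EPS:
                return pairs
            found = False
            for p in range(i - 1, max(-1, i - 2 - params.max_loop), -1):
                gx = i - p - 1
                for q in range(j + 1, min(ya.size, j + 2 + params.max_loop - gx)):
                    gy = q - j - 1
                    if gx == 0 and gy == 0:
                        continue
                    prev = P2[p, q] if params.no_lonely_pairs else min(
                        P1[p, q], P2[p, q]
                    )
                    if prev < INF / 2 and abs(
                        target - (prev + params.loop_open
                                  + params.loop_per_base * (gx + gy))
                    ) <= _EPS:
                        i, j, found = p, q, True
                        in_p2 = params.no_lonely_pairs or P2[p, q] <= P1[p, q] + _EPS
                        pairs.append((i, j))
                        break
                if found:
                    break
            if not found:  # pragma: no cover - defensive
                raise AssertionError("duplex traceback lost (loop)")


def conserved_concat(
    iv: GenomicInterval, elems: IntervalSet, store: SequenceStore
) -> ConservedConcat:
    """Concatenation of the conserved parts of ``iv``.

    Segments are the merged intersections of ``iv`` with the element set,
    ordered 5'->3' of the pre-mRNA (descending genomic coordinate on the
    minus strand, each segment reverse-complemented).
    """
    pieces = elems.intersect(iv)
    if iv.strand == "-":
        pieces = pieces[::-1]
    seq_parts: list[str] = []
    segmap: list[tuple[int, GenomicInterval]] = []
    off = 0
    for s, e in pieces:
        seg = GenomicInterval(iv.chrom, s, e, iv.strand)
        seq_parts.append(extract_sequence(seg, store))
        segmap.append((off, seg))
        off += e - s
    return ConservedConcat("".join(seq_parts), segmap)


def _control_pair(
    x: str,
    y: str,
    control: str,
    rng: np.random.Generator,
    pool: list[str] | None,
) -> tuple[str, str]:
    if control == "shuffle":
        sx = shuffle(x, ShuffleConfig(seed=int(rng.integers(2**31))))
        sy = shuffle(y, ShuffleConfig(seed=int(rng.integers(2**31))))
        return sx, sy
    if control == "length_matched":
        if not pool or len(pool) < 2:
            raise ValueError("length_matched control requires a sequence pool")
        cx = length_matched_control_seq(x, pool, rng)
        cy = length_matched_control_seq(y, pool, rng)
        return cx, cy
    raise ValueError(f"unknown control mode {control!r}")


def length_matched_control_seq(
    query: str, pool: list[str], rng: np.random.Generator
) -> str:
    """Length-matched draw from a pool sorted by ascending length."""
    from bisect import bisect_left

    lengths = [len(s) for s in pool]
    rank = bisect_left(lengths, len(query))
    rank = min(rank, len(pool) - 1)
    from .similarity import length_matched_control

    return length_matched_control(rank, pool, rng)


def ddg(
    x: str,
    y: str,
    control: str = "shuffle",
    params: EnergyParams | None = None,
    rng: np.random.Generator | None = None,
    pool: list[str] | None = None,
    threshold: float = 30.0,
    n_controls: int = 1,
) -> HybridizationResult:
    """ΔΔG = ΔG(x, y) − ΔG(control pair); |ΔΔG| > threshold is discarded.

    With ``n_controls`` > 1 the control energy is the median over that
    many independently drawn control pairs.
    """
    params = params or EnergyParams()
    rng = rng if rng is not None else np.random.default_rng(1)
    dG, site_x, site_y = duplex_mfe(x, y, params)
    dG0s = []
    for _ in range(n_controls):
        cx, cy = _control_pair(x, y, control, rng, pool)
        dG0s.append(duplex_mfe(cx, cy, params)[0])
    dG0 = float(np.median(dG0s))
    d = dG - dG0
    return HybridizationResult(
        dG=dG, dG0=dG0, ddG=d, site_x=site_x, site_y=site_y,
        discarded=abs(d) > threshold,
    )


@dataclass
class ScanRow:
    cluster_id: str
    gene_id: str
    pair_class: PairClass
    i: int
    j: int
    result: HybridizationResult
    sites_x_genomic: list[GenomicInterval]
    sites_y_genomic: list[GenomicInterval]


def cluster_hybridization_scan(
    cluster: MxeCluster,
    elems: IntervalSet,
    store: SequenceStore,
    params: EnergyParams | None = None,
    rng: np.random.Generator | None = None,
    control: str = "shuffle",
    threshold: float = 30.0,
    pool: list[str] | None = None,
    n_controls: int = 1,
    max_len: int = 10_000,
) -> list[ScanRow]:
    """ΔΔG rows for all flank-vs-internal and internal-vs-internal intron
    pairs of one cluster, on conserved-part concatenations.

    For a cluster of n exons the introns are numbered 0 (left) .. n
    (right); internal introns are 1..n-1. Rows with an empty conserved
    concatenation, an N-containing window, or a sequence longer than
    ``max_len`` are skipped (logged).
    """
    params = params or EnergyParams()
    rng = rng if rng is not None else np.random.default_rng(1)
    n = cluster.n
    concats = [conserved_concat(iv, elems, store) for iv in cluster.introns]

    def usable(k: int) -> bool:
        s = concats[k].sequence
        if not s:
            log.debug("%s intron %d: empty conserved concat", cluster.id, k)
            return False
        if "N" in s:
            log.debug("%s intron %d: N in window, skipped", cluster.id, k)
            return False
        if len(s) > max_len:
            log.debug("%s intron %d: longer than cap, skipped", cluster.id, k)
            return False
        return True

    tasks: list[tuple[PairClass, int, int]] = []
    for i in range(1, n):
        tasks.append((PairClass.L_to_i, 0, i))
    for i in range(1, n):
        for j in range(i + 1, n):
            tasks.append((PairClass.i_to_j, i, j))
    for j in range(1, n):
        tasks.append((PairClass.j_to_R, j, n))

    rows = []
    for pc, i, j in tasks:
        if not (usable(i) and usable(j)):
            continue
        cx, cy = concats[i], concats[j]
        res = ddg(
            cx.sequence, cy.sequence, control=control, params=params,
            rng=rng, pool=pool, threshold=threshold, n_controls=n_controls,
        )
        sx = cx.map_back(*res.site_x) if res.site_x else []
        sy = cy.map_back(*res.site_y) if res.site_y else []
        rows.append(
            ScanRow(
                cluster_id=cluster.id, gene_id=cluster.gene_id,
                pair_class=pc, i=i, j=j, result=res,
                sites_x_genomic=sx, sites_y_genomic=sy,
            )
        )
    return rows


def docker_site_map(rows: list[ScanRow]) -> list[tuple[str, int, int, str, int, str]]:
    """BED6 records of predicted docker sites on the flanking introns.

    For each cluster flank (left intron of L_to_i rows, right intron of
    j_to_R rows), duplex site intervals across internal partners are
    merged when overlapping; the score is the number of partner rows
    whose site overlaps the merged interval.
    """
    per_flank: dict[tuple[str, str], list[tuple[GenomicInterval, int]]] = {}
    for row in rows:
        if row.result.discarded:
            continue
        if row.pair_class == PairClass.L_to_i:
            sites, flank = row.sites_x_genomic, "left"
        elif row.pair_class == PairClass.j_to_R:
            sites, flank = row.sites_y_genomic, "right"
        else:
            continue
        key = (row.cluster_id, flank)
        for iv in sites:
            per_flank.setdefault(key, []).append((iv, row.j if flank == "left" else row.i))

    records = []
    for (cluster_id, flank), tagged in sorted(per_flank.items()):
        tagged.sort(key=lambda t: (t[0].start, t[0].end))
        merged: list[list] = []  # [start, end, set(partners), chrom, strand]
        for iv, partner in tagged:
            if merged and iv.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], iv.end)
                merged[-1][2].add(partner)
            else:
                merged.append([iv.start, iv.end, {partner}, iv.chrom, iv.strand])
        for k, (s, e, partners, chrom, strand) in enumerate(merged):
            records.append(
                (chrom, s, e, f"{cluster_id}:{flank}_docker_{k}",
                 len(partners), strand)
            )
    return records


def external_duplex_mfe(
    x: str, y: str, exe: str = "RNAduplex", args: tuple[str, ...] = ("--noLP",)
) -> tuple[float, tuple[int, int] | None, tuple[int, int] | None]:
    """Adapter: fold one pair with an external duplex tool.

    Runs an RNAduplex/RNAplex-style executable (two sequences on stdin,
    one result line ``structure  i,j : k,l (energy)``) and returns
    (dG, site_x, site_y) in the same convention as :func:`duplex_mfe`
    (0-based half-open sites). T is transcribed to U on the way in.
    """
    import re
    import subprocess

    inp = f"{x.upper().replace('T', 'U')}\n{y.upper().replace('T', 'U')}\n"
    out = subprocess.run(
        [exe, *args], input=inp, capture_output=True, text=True, check=True
    ).stdout
    m = re.search(
        r"(\d+),(\d+)\s*:\s*(\d+),(\d+)\s*\(\s*(-?\d+\.?\d*)\s*\)", out
    )
    if not m:
        return 0.0, None, None
    i1, i2, j1, j2, e = m.groups()
    return float(e), (int(i1) - 1, int(i2)), (int(j1) - 1, int(j2))
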