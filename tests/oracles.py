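"""Independent brute-force oracles used by the test suite.

These deliberately avoid the dynamic-programming shortcuts of the package
implementations: local alignment is scored by enumerating every alignment
path, duplex MFE by enumerating every legal structure, and independent
path counts by exhaustive subset search.
"""

from __future__ import annotations

from itertools import combinations

from mxefold.energies import EnergyParams, _ENC
from mxefold.similarity import AlignScoring

_WC = {(0, 3), (3, 0), (1, 2), (2, 1)}
_GU = {(2, 3), (3, 2)}


def sw_bruteforce(x: str, y: str, sc: AlignScoring) -> float:
    """Best local-alignment score by exhaustive path enumeration."""
    best = 0.0
    n, m = len(x), len(y)

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            s = sc.match if x[i] == y[j] else sc.mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < n:
            cost = sc.gap_extend if last == "X" else sc.gap_open
            rec(i + 1, j, score + cost, "X")
        if j < m:
            cost = sc.gap_extend if last == "Y" else sc.gap_open
            rec(i, j + 1, score + cost, "Y")

    for i in range(n):
        for j in range(m):
            rec(i, j, 0.0, "")
    return best


def duplex_bruteforce(x: str, y: str, params: EnergyParams) -> float | None:
    """Minimum duplex energy by enumerating every legal structure.

    Returns None when no legal structure exists (the DP then reports 0
    with no site).
    """
    xe = [_ENC[c] for c in x]
    ye = [_ENC[c] for c in y]
    pairs = _WC | (_GU if params.allow_gu else set())

    def pairable(a: int, b: int) -> bool:
        return (a, b) in pairs

    n, m = len(xe), len(ye)
    best: list[float | None] = [None]

    def rec(i: int, j: int, energy: float, helix: int) -> None:
        # candidate structure ends here
        if helix >= (2 if params.no_lonely_pairs else 1):
            if best[0] is None or energy < best[0]:
                best[0] = energy
        # stack extension
        if i + 1 < n and j - 1 >= 0 and pairable(xe[i + 1], ye[j - 1]):
            rec(i + 1, j - 1,
                energy + params._stack[xe[i], ye[j], xe[i + 1], ye[j - 1]],
                helix + 1)
        # close this helix with a loop and start a new one
        if helix >= (2 if params.no_lonely_pairs else 1):
            for p in range(i + 1, n):
                for q in range(j - 1, -1, -1):
                    gap = (p - i - 1) + (j - q - 1)
                    if gap < 1 or gap > params.max_loop:
                        continue
                    if pairable(xe[p], ye[q]):
                        rec(p, q, energy + params.loop_open
                            + params.loop_per_base * gap, 1)

    for i in range(n):
        for j in range(m):
            if pairable(xe[i], ye[j]):
                rec(i, j, params.init, 1)
    return best[0]


def independent_ie_paths_bruteforce(
    exon_edges: set[tuple[int, int]],
    intron_edges: set[tuple[int, int]],
    u: int,
    v: int,
) -> int:
    """Maximum number of internally-disjoint intron-exon-intron paths
    from splice site u to splice site v, by exhaustive subset search.

    Internal nodes of a path are the two splice sites of its middle
    exon, labelled by genomic side so that an exon end and an exon start
    at the same coordinate are distinct nodes.
    """
    middles = [
        (s, e) for (s, e) in exon_edges
        if u < s < e < v and (u, s) in intron_edges and (e, v) in intron_edges
    ]
    best = 0
    for k in range(len(middles), 0, -1):
        for subset in combinations(middles, k):
            nodes = [(s, "L") for s, _ in subset] + [(e, "R") for _, e in subset]
            if len(nodes) == len(set(nodes)):
                best = k
                break
        if best:
            break
    return best
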