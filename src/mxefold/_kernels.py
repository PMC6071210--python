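"""Numba kernels: intermolecular duplex DP and dinucleotide shuffle.

Sequences are int8 arrays with A=0, C=1, G=2, T/U=3.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e30


@njit(cache=True)
def duplex_dp(x, y, pairable, stack, loop_open, loop_c, init, max_loop, nolp):
    """Minimum-free-energy intermolecular duplex between x and y.

    A duplex is a chain of base pairs (i, j), i ascending on x and j
    descending on y, grouped into helices of stacked pairs separated by
    interior/bulge loops of 1..max_loop total unpaired bases charged
    loop_open per loop plus loop_c per base, plus one initiation penalty. With nolp every helix
    must contain at least two stacked pairs.

    Returns (P1, P2): P1[i, j] is the best energy of a duplex whose last
    pair (i, j) is the first pair of its helix; P2[i, j] requires the last
    pair to be stacked on the previous one.
    """
    n, m = x.size, y.size
    P1 = np.full((n, m), INF)
    P2 = np.full((n, m), INF)
    for i in range(n):
        for j in range(m):
            if not pairable[x[i], y[j]]:
                continue
            # helix start: either duplex initiation or close of a loop
            best = init
            pmin = i - 1 - max_loop
            if pmin < 0:
                pmin = 0
            for p in range(i - 1, pmin - 1, -1):
                gx = i - p - 1
                qmax = j + 1 + (max_loop - gx)
                if qmax > m - 1:
                    qmax = m - 1
                for q in range(j + 1, qmax + 1):
                    gy = q - j - 1
                    if gx == 0 and gy == 0:
                        continue
                    if nolp:
                        e = P2[p, q]
                    else:
                        e = min(P1[p, q], P2[p, q])
                    if e < INF / 2:
                        cand = e + loop_open + loop_c * (gx + gy)
                        if cand < best:
                            best = cand
            P1[i, j] = best
            # helix extension
            if i >= 1 and j <= m - 2 and pairable[x[i - 1], y[j + 1]]:
                prev = min(P1[i - 1, j + 1], P2[i - 1, j + 1])
                if prev < INF / 2:
                    P2[i, j] = stack[x[i - 1], y[j + 1], x[i], y[j]] + prev
    return P1, P2


@njit(cache=True)
def dinuc_shuffle_kernel(arr, n_swaps, seed):
    """In-place dinucleotide-preserving shuffle.

    Each move picks an interior position i uniformly, then a partner j
    uniformly among interior positions with the same outer-letter context
    (arr[j-1] == arr[i-1] and arr[j+1] == arr[i+1]) and |j - i| >= 2, and
    exchanges the middle letters. Overlapping contexts (|j - i| < 2) are
    excluded because exchanging overlapping triplets does not preserve
    dinucleotide counts. Moves without an eligible partner are no-ops that
    still count toward n_swaps.
    """
    np.random.seed(seed)
    l = arr.size
    if l < 3:
        return
    nint = l - 2
    bucket = np.empty((16, nint), np.int64)
    bsize = np.zeros(16, np.int64)
    slot = np.empty(l, np.int64)
    ctx = np.empty(l, np.int64)
    for i in range(1, l - 1):
        c = 4 * arr[i - 1] + arr[i + 1]
        ctx[i] = c
        slot[i] = bsize[c]
        bucket[c, bsize[c]] = i
        bsize[c] += 1

    touched = np.empty(4, np.int64)
    for _ in range(n_swaps):
        i = 1 + np.random.randint(nint)
        c = ctx[i]
        sz = bsize[c]
        if sz < 2:
            continue
        eligible = 0
        for k in range(sz):
            jj = bucket[c, k]
            if jj < i - 1 or jj > i + 1:
                eligible += 1
        if eligible == 0:
            continue
        r = np.random.randint(eligible)
        j = -1
        cnt = 0
        for k in range(sz):
            jj = bucket[c, k]
            if jj < i - 1 or jj > i + 1:
                if cnt == r:
                    j = jj
                    break
                cnt += 1
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp
        # contexts of i and j are unchanged; their neighbours' outer
        # letters changed, so rebucket those
        touched[0] = i - 1
        touched[1] = i + 1
        touched[2] = j - 1
        touched[3] = j + 1
        for k in range(4):
            p = touched[k]
            if p < 1 or p > l - 2:
                continue
            newc = 4 * arr[p - 1] + arr[p + 1]
            oldc = ctx[p]
            if newc == oldc:
                continue
            sp = slot[p]
            last = bsize[oldc] - 1
            moved = bucket[oldc, last]
            bucket[oldc, sp] = moved
            slot[moved] = sp
            bsize[oldc] = last
            ctx[p] = newc
            slot[p] = bsize[newc]
            bucket[newc, bsize[newc]] = p
            bsize[newc] += 1
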