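"""Numba dynamic-programming kernels for local and global alignment.

Sequences are int8 code arrays (A=0, C=1, G=2, T=3; anything >= 4 never
matches). Affine gap convention: a length-k gap costs |gap_open| + k *
|gap_extend| (the open penalty is charged once, every gapped base pays the
extend penalty).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1_000_000


@njit(cache=True)
def sw_align(q, r, match, mismatch, gap_open, gap_extend):
    """Smith-Waterman local alignment with affine gaps.

    Returns (score, q_start, q_end, r_start, r_end, n_mismatch, n_gap) with
    half-open [start, end) intervals. Among equal-scoring cells the one with
    the largest query end, then largest reference end, is chosen (maximal
    extension toward the 3' terminus, which the terminus caller reads off the
    alignment end). Returns all zeros when nothing scores above 0.
    """
    n = q.shape[0]
    m = r.shape[0]
    open_cost = -(gap_open + gap_extend)  # positive cost of the first gapped base
    ext_cost = -gap_extend
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)  # gap in query (consumes ref)
    F = np.full((n + 1, m + 1), NEG, np.int32)  # gap in ref (consumes query)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - open_cost
            if E[i, j - 1] - ext_cost > e:
                e = E[i, j - 1] - ext_cost
            E[i, j] = e
            f = H[i - 1, j] - open_cost
            if F[i - 1, j] - ext_cost > f:
                f = F[i - 1, j] - ext_cost
            F[i, j] = f
            if qc == r[j - 1] and qc < 4:
                h = H[i - 1, j - 1] + match
            else:
                h = H[i - 1, j - 1] + mismatch
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best or (h == best and h > 0 and (i > bi or (i == bi and j > bj))):
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback with state machine; diagonal preferred on ties (fewer gaps)
    i = bi
    j = bj
    n_mm = 0
    n_gap = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            eq = q[i - 1] == r[j - 1] and q[i - 1] < 4
            s = match if eq else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                if not eq:
                    n_mm += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_gap += 1
            if E[i, j] == H[i, j - 1] - open_cost:
                state = 0
            j -= 1
        else:
            n_gap += 1
            if F[i, j] == H[i - 1, j] - open_cost:
                state = 0
            i -= 1
    return best, i, bi, j, bj, n_mm, n_gap


@njit(cache=True)
def nw_align(a, b, match, mismatch, gap):
    """Needleman-Wunsch global alignment with a linear gap penalty.

    Returns (score, ops) where ops is an int8 array over the alignment
    columns: 0 = aligned pair, 1 = gap in b (consumes a), 2 = gap in a
    (consumes b). Traceback prefers aligned pairs on ties, which keeps the
    gap count minimal among co-optimal paths and is deterministic.
    """
    n = a.shape[0]
    m = b.shape[0]
    S = np.empty((n + 1, m + 1), np.int32)
    for i in range(n + 1):
        S[i, 0] = i * gap
    for j in range(m + 1):
        S[0, j] = j * gap
    for i in range(1, n + 1):
        ac = a[i - 1]
        for j in range(1, m + 1):
            if ac == b[j - 1] and ac < 4:
                s = S[i - 1, j - 1] + match
            else:
                s = S[i - 1, j - 1] + mismatch
            up = S[i - 1, j] + gap
            if up > s:
                s = up
            left = S[i, j - 1] + gap
            if left > s:
                s = left
            S[i, j] = s
    ops = np.empty(n + m, np.int8)
    k = 0
    i = n
    j = m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            eq = a[i - 1] == b[j - 1] and a[i - 1] < 4
            s = match if eq else mismatch
            if S[i, j] == S[i - 1, j - 1] + s:
                ops[k] = 0
                i -= 1
                j -= 1
                k += 1
                continue
        if i > 0 and S[i, j] == S[i - 1, j] + gap:
            ops[k] = 1
            i -= 1
            k += 1
            continue
        ops[k] = 2
        j -= 1
        k += 1
    return S[n, m], ops[:k][::-1].copy()
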