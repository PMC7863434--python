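"""Affine-gap Smith-Waterman kernel (numba-compiled).

Gap model: a gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the
first gapped base pays the open penalty). Bases are 2-bit codes 0..3; code 4
(N) never matches anything, including another N.

Pointer encoding per DP cell (uint8):
  bits 0-1: source of H  (0 = local start, 1 = diagonal, 2 = E, 3 = F)
  bit 2:    E opened from H (else extended from E)
  bit 3:    F opened from H (else extended from F)
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**8)


@njit(cache=True)
def sw_affine(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    # rolling 1-D score rows; only the pointer matrix is kept for traceback
    h_prev = np.zeros(m + 1, np.int32)
    h_cur = np.zeros(m + 1, np.int32)
    f_col = np.full(m + 1, NEG, np.int32)  # gap in target (I), carried down rows
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        h_cur[0] = 0
        e = NEG  # gap in query (D), carried along the row
        for j in range(1, m + 1):
            flags = 0
            eo = h_cur[j - 1] + gap_open
            ee = e + gap_extend
            if eo >= ee:
                e = eo
                flags |= 4
            else:
                e = ee
            fo = h_prev[j] + gap_open
            fe = f_col[j] + gap_extend
            if fo >= fe:
                f_col[j] = fo
                flags |= 8
            else:
                f_col[j] = fe
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            d = h_prev[j - 1] + s
            h = 0
            src = 0
            if d > h:
                h = d
                src = 1
            if e > h:
                h = e
                src = 2
            if f_col[j] > h:
                h = f_col[j]
                src = 3
            h_cur[j] = h
            ptr[i, j] = np.uint8(src | flags)
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj, ptr


@njit(cache=True)
def kmer_hit_counts(reads, kmers_sorted, k, stride):  # pragma: no cover - jitted
    """Per-read count of sampled k-mers present in a sorted k-mer code set."""
    n, L = reads.shape
    m = kmers_sorted.shape[0]
    out = np.zeros(n, np.int32)
    for i in range(n):
        cnt = 0
        for off in range(0, L - k + 1, stride):
            code = np.int64(0)
            valid = True
            for t in range(k):
                b = reads[i, off + t]
                if b >= 4:
                    valid = False
                    break
                code = code * 4 + b
            if not valid:
                continue
            lo = 0
            hi = m
            while lo < hi:
                mid = (lo + hi) // 2
                if kmers_sorted[mid] < code:
                    lo = mid + 1
                else:
                    hi = mid
            if lo < m and kmers_sorted[lo] == code:
                cnt += 1
        out[i] = cnt
    return out


def traceback(q, t, ptr, bi, bj):
    """Walk pointers from the best cell; return (ops, matches, qstart, tstart).

    ``ops`` is the alignment column list in 5'->3' query order, each element
    one of 'M', 'I' (gap in target, consumes query) or 'D' (gap in query,
    consumes target). ``matches`` counts identical non-N columns.
    """
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    rev_ops: list[str] = []
    matches = 0
    while True:
        p = ptr[i, j]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                rev_ops.append("M")
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            rev_ops.append("D")
            opened = p & 4
            j -= 1
            if opened:
                state = 0
        else:
            rev_ops.append("I")
            opened = p & 8
            i -= 1
            if opened:
                state = 0
    rev_ops.reverse()
    return rev_ops, matches, i, j
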