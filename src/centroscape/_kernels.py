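"""Numba kernel for banded local alignment.

The production aligner resolves each seed cluster with a banded local Gotoh
dynamic programme.  The band is expressed in diagonal space: a cell (i, j)
(i query characters, j target characters consumed) is inside the band iff
dlo <= j - i <= dhi.  Scores are affine: a gap of length L scores
gap_open + (L - 1) * gap_extend (both negative).

Score rows are rolled (only the previous row is kept); traceback pointers
are bit-packed into one uint8 matrix: bits 0-1 the H-state move (stop /
diagonal / from-E / from-F), bit 2 whether E extended, bit 3 whether F
extended.
"""

import numpy as np
from numba import njit

NEG = -(10**9)

_STOP = 0
_DIAG = 1
_FROM_E = 2
_FROM_F = 3


@njit(cache=True, nogil=True)
def banded_local_align(q, t, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Best local alignment of q vs t restricted to diagonals [dlo, dhi].

    q, t are uint8 code arrays (A=0 C=1 G=2 T=3, anything >=4 never
    matches).  Returns (score, qstart, qend, tstart, tend, matches,
    columns) with 0-based half-open intervals; score == 0 means no
    positive-scoring alignment exists inside the band.
    """
    n = q.size
    m = t.size
    W = dhi - dlo + 1
    h_prev = np.full(W, NEG, np.int32)
    h_cur = np.full(W, NEG, np.int32)
    f_prev = np.full(W, NEG, np.int32)
    f_cur = np.full(W, NEG, np.int32)
    ptr = np.zeros((n + 1, W), np.uint8)

    # row 0: local starts wherever the cell is valid
    for b in range(W):
        j = 0 + dlo + b
        if 0 <= j <= m:
            h_prev[b] = 0

    best = 0
    bi = 0
    bb = -1
    half_neg = NEG // 2
    for i in range(1, n + 1):
        for b in range(W):
            h_cur[b] = NEG
            f_cur[b] = NEG
        # valid cells this row: 0 <= j <= m with j = i + dlo + b
        blo = -i - dlo
        if blo < 0:
            blo = 0
        bhi = m - i - dlo
        if bhi > W - 1:
            bhi = W - 1
        qc = q[i - 1]
        e_run = NEG
        for b in range(blo, bhi + 1):
            j = i + dlo + b
            if j == 0:
                h_cur[b] = 0
                e_run = NEG
                continue
            code = np.uint8(0)
            # E: gap consuming target, predecessor (i, j-1) = (i, b-1)
            e_val = NEG
            if b > 0:
                open_e = h_cur[b - 1] + gap_open
                ext_e = e_run + gap_extend
                if ext_e > open_e:
                    e_val = ext_e
                    code |= np.uint8(4)
                else:
                    e_val = open_e
            # F: gap consuming query, predecessor (i-1, j) = (i-1, b+1)
            f_val = NEG
            if b + 1 < W:
                open_f = h_prev[b + 1] + gap_open
                ext_f = f_prev[b + 1] + gap_extend
                if ext_f > open_f:
                    f_val = ext_f
                    code |= np.uint8(8)
                else:
                    f_val = open_f
            f_cur[b] = f_val
            # H: diagonal predecessor (i-1, j-1) = (i-1, b)
            tc = t[j - 1]
            d_val = h_prev[b]
            if d_val > half_neg:
                d_val += match if (qc == tc and qc < 4) else mismatch
            h = 0
            p = _STOP
            if d_val > h:
                h = d_val
                p = _DIAG
            if e_val > h:
                h = e_val
                p = _FROM_E
            if f_val > h:
                h = f_val
                p = _FROM_F
            h_cur[b] = h
            e_run = e_val
            ptr[i, b] = code | np.uint8(p)
            if h > best:
                best = h
                bi = i
                bb = b
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    i = bi
    b = bb
    qe = bi
    te = bi + dlo + bb
    n_match = 0
    n_cols = 0
    state = 0  # 0=H 1=E 2=F
    while i > 0 and 0 < i + dlo + b:
        code = ptr[i, b]
        if state == 0:
            p = code & np.uint8(3)
            if p == _STOP:
                break
            if p == _DIAG:
                qc = q[i - 1]
                tc = t[i + dlo + b - 1]
                n_cols += 1
                if qc == tc and qc < 4:
                    n_match += 1
                i -= 1
            elif p == _FROM_E:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_cols += 1
            ext = code & np.uint8(4)
            b -= 1
            state = 1 if ext else 0
        else:
            n_cols += 1
            ext = code & np.uint8(8)
            i -= 1
            b += 1
            state = 2 if ext else 0
    qb = i
    tb = i + dlo + b
    return best, qb, qe, tb, te, n_match, n_cols
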