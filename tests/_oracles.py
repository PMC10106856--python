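"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results with exhaustive, unoptimised
algorithms (full dynamic-programming matrices, per-base counting,
permutation resampling) so the production code paths are checked against
structurally different implementations.
"""

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def full_local_gotoh(q, t, match, mismatch, gap_open, gap_extend):
    """Exhaustive local Gotoh: full (n+1) x (m+1) matrices, no band, no seeds.

    Returns (score, qstart, qend, tstart, tend, matches, columns) of the
    best local alignment; ties resolved by the first-reached maximum in
    row-major order.
    """
    n = q.size
    m = t.size
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e1 = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            E[i, j] = e1 if e1 >= e2 else e2
            f1 = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            F[i, j] = f1 if f1 >= f2 else f2
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if h < 0:
                h = 0
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback by state reconstruction
    i, j = bi, bj
    n_match = 0
    n_cols = 0
    state = 0  # 0=H 1=E 2=F
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                n_cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_cols += 1
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:
            n_cols += 1
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
    return best, i, bi, j, bj, n_match, n_cols


def edit_distance_nw(a: str, b: str) -> int:
    """Unbanded unit-cost global alignment distance, row-vectorised."""
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), np.uint8)
    bv = np.frombuffer(b.encode(), np.uint8)
    prev = np.arange(m + 1, dtype=np.int32)
    idx = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        cur = np.empty(m + 1, np.int32)
        cur[0] = i
        sub = prev[:-1] + (av[i - 1] != bv).astype(np.int32)
        dele = prev[1:] + 1
        cur[1:] = np.minimum(sub, dele)
        # insertion chain cur[j] <- min_{i<=j} cur[i] + (j - i) as a prefix scan
        cur = np.minimum(cur, np.minimum.accumulate(cur - idx) + idx)
        prev = cur
    return int(prev[m])


def coverage_per_base(region_intervals, feature_intervals) -> float:
    """Per-base counting oracle for coverage_fraction."""
    hi = max(e for _, e in region_intervals)
    region_mask = np.zeros(hi, bool)
    for s, e in region_intervals:
        region_mask[s:e] = True
    feat_mask = np.zeros(hi, bool)
    for s, e in feature_intervals:
        feat_mask[s : min(e, hi)] = True
    denom = region_mask.sum()
    return float((region_mask & feat_mask).sum() / denom)


def permutation_t_pvalue(a, b, n_perm: int, seed: int) -> float:
    """Two-sided permutation p-value for the difference in means."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        d = abs(pooled[: a.size].mean() - pooled[a.size :].mean())
        if d >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def window_coverage_brute(intervals, lo: int, hi: int) -> int:
    """Covered bp of [lo, hi) by a union of intervals, counted per base."""
    mask = np.zeros(hi - lo, bool)
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            mask[s2 - lo : e2 - lo] = True
    return int(mask.sum())
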