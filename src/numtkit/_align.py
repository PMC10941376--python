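"""Numba kernels for alignment: banded x-drop extension, full
Smith-Waterman with origin tracking, and the ungapped-segment counter used
for Karlin K calibration."""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def xdrop_extend(s, q, i0, j0, direction, match, mismatch, gap_open,
                 gap_extend, xdrop, width):  # pragma: no cover - numba
    """Banded affine-gap x-drop extension.

    Extends an alignment anchored at (i0, j0): rightwards over
    ``s[i0:], q[j0:]`` when ``direction`` is +1, leftwards over
    ``s[:i0], q[:j0]`` when -1.  The band covers diagonal offsets
    ``(q consumed) - (s consumed)`` in [-width, width].  Returns
    ``(best_score, s_consumed, q_consumed)`` for the best-scoring
    extension endpoint.
    """
    B = 2 * width + 1
    H = np.full(B, NEG, dtype=np.int64)
    E = np.full(B, NEG, dtype=np.int64)
    F = np.full(B, NEG, dtype=np.int64)
    H[width] = 0
    if direction > 0:
        s_avail = s.shape[0] - i0
        q_avail = q.shape[0] - j0
    else:
        s_avail = i0
        q_avail = j0
    best = 0
    best_t = 0
    best_k = width
    go_ge = gap_open + gap_extend

    # t = subject chars consumed; in-column pass handles query-only gaps
    t = 0
    # first, query-only gaps in column 0 (alignments starting with a gap
    # never help under negative gap scores, so column 0 stays as-is)
    max_t = s_avail
    while t < max_t:
        t += 1
        if direction > 0:
            sc = s[i0 + t - 1]
        else:
            sc = s[i0 - t]
        Hn = np.full(B, NEG, dtype=np.int64)
        En = np.full(B, NEG, dtype=np.int64)
        Fn = np.full(B, NEG, dtype=np.int64)
        col_best = NEG
        for k in range(B):
            j = t + k - width  # query chars consumed at this cell
            if j < 0 or j > q_avail:
                continue
            # deletion in query axis (consume s only): from column t-1, k+1
            if k + 1 < B:
                f1 = H[k + 1] + go_ge
                f2 = F[k + 1] + gap_extend
                Fn[k] = f1 if f1 > f2 else f2
            # diagonal: consume both
            diag = NEG
            if j >= 1:
                if direction > 0:
                    qc = q[j0 + j - 1]
                else:
                    qc = q[j0 - j]
                if H[k] > NEG // 2:
                    if sc == qc and sc < 4:
                        diag = H[k] + match
                    else:
                        diag = H[k] + mismatch
            # insertion in query axis (consume q only): same column, k-1
            if k >= 1 and j >= 1:
                e1 = Hn[k - 1] + go_ge
                e2 = En[k - 1] + gap_extend
                En[k] = e1 if e1 > e2 else e2
            h = diag
            if En[k] > h:
                h = En[k]
            if Fn[k] > h:
                h = Fn[k]
            Hn[k] = h
            if h > col_best:
                col_best = h
            if h > best:
                best = h
                best_t = t
                best_k = k
        if col_best < best - xdrop:
            break
        H, E, F = Hn, En, Fn
    return best, best_t, best_t + best_k - width


@njit(cache=True)
def smith_waterman(a, b, match, mismatch, gap_open,
                   gap_extend):  # pragma: no cover - numba
    """Full affine-gap local alignment DP with origin tracking.

    Returns (score, a_start, a_end, b_start, b_end) of the best local
    alignment (first-encountered maximum in row-major order).
    """
    n, m = a.shape[0], b.shape[0]
    go_ge = gap_open + gap_extend
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    # origins: start coordinates of the path reaching each cell
    Hoa = np.zeros(m + 1, dtype=np.int64)
    Hob = np.zeros(m + 1, dtype=np.int64)
    Eoa = np.zeros(m + 1, dtype=np.int64)
    Eob = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, NEG, dtype=np.int64)
    Foa = np.zeros(m + 1, dtype=np.int64)
    Fob = np.zeros(m + 1, dtype=np.int64)
    for j in range(m + 1):
        Hob[j] = j
    best = 0
    ba = be = bb = bbe = 0
    boa = 0
    bob = 0
    for i in range(1, n + 1):
        diag_H = H[0]
        diag_oa, diag_ob = Hoa[0], Hob[0]
        H[0] = 0
        Hoa[0] = i
        Hob[0] = 0
        E[0] = NEG
        for j in range(1, m + 1):
            # F: gap in b (consume a only), column-wise
            f1 = H[j] + go_ge
            f2 = F[j] + gap_extend
            if f1 >= f2:
                F[j] = f1
                Foa[j], Fob[j] = Hoa[j], Hob[j]
            else:
                F[j] = f2
            # E: gap in a (consume b only), row-wise
            e1 = H[j - 1] + go_ge
            e2 = E[j - 1] + gap_extend
            if e1 >= e2:
                E[j] = e1
                Eoa[j], Eob[j] = Hoa[j - 1], Hob[j - 1]
            else:
                E[j] = e2
                Eoa[j], Eob[j] = Eoa[j - 1], Eob[j - 1]
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                d = diag_H + match
            else:
                d = diag_H + mismatch
            doa, dob = diag_oa, diag_ob
            h = d
            hoa, hob = doa, dob
            if E[j] > h:
                h = E[j]
                hoa, hob = Eoa[j], Eob[j]
            if F[j] > h:
                h = F[j]
                hoa, hob = Foa[j], Fob[j]
            if h < 0:
                h = 0
                hoa, hob = i, j
            diag_H = H[j]
            diag_oa, diag_ob = Hoa[j], Hob[j]
            H[j] = h
            Hoa[j] = hoa
            Hob[j] = hob
            if h > best:
                best = h
                ba, bb = hoa, hob
                be, bbe = i, j
    return best, ba, be, bb, bbe


@njit(cache=True)
def count_high_segments(a, b, match, mismatch,
                        thresholds):  # pragma: no cover - numba
    """Count maximal ungapped segments with score >= each threshold.

    Kadane scan along every diagonal of the a-vs-b comparison; used to
    calibrate the Karlin K prefactor by Monte-Carlo.
    """
    n, m = a.shape[0], b.shape[0]
    counts = np.zeros(thresholds.shape[0], dtype=np.int64)
    for d in range(-(n - 1), m):
        if d >= 0:
            i, j = 0, d
        else:
            i, j = -d, 0
        cur = 0
        seg_max = 0
        while i < n and j < m:
            if a[i] == b[j] and a[i] < 4:
                cur += match
            else:
                cur += mismatch
            if cur <= 0:
                if seg_max > 0:
                    for t in range(thresholds.shape[0]):
                        if seg_max >= thresholds[t]:
                            counts[t] += 1
                cur = 0
                seg_max = 0
            elif cur > seg_max:
                seg_max = cur
            i += 1
            j += 1
        if seg_max > 0:
            for t in range(thresholds.shape[0]):
                if seg_max >= thresholds[t]:
                    counts[t] += 1
    return counts
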