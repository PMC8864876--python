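"""Numba DP kernel for local alignment (Gotoh affine gaps).

The kernel runs in O(n*m) time and O(m) memory over the target (read or
contig window) x query (adapter) matrix, returning only the best score and
the target interval of one maximum-scoring alignment; column-level counts
are recovered afterwards by a small traceback pass on that interval (see
``aligner``).  Base codes: 0..3 = ACGT, >= 4 (N, mask) mismatches
everything including itself.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(1 << 40)


@njit(cache=True, nogil=True)
def sw_best(t, q, match, mismatch, gap_open, gap_ext):  # pragma: no cover - jit
    """Best local alignment of query ``q`` inside target ``t``.

    Returns ``(score, t_start, t_end)`` with 0-based, end-exclusive target
    coordinates; ``(0, -1, -1)`` when no alignment scores above zero.
    A gap of length k costs ``gap_open + k * gap_ext``.  Ties are broken
    toward the smaller target start, then the smaller target end.
    """
    n = t.size
    m = q.size
    H = np.zeros(m + 1, np.int64)
    SH = np.zeros(m + 1, np.int64)  # target start of alignment ending at H cell
    E = np.full(m + 1, NEG, np.int64)  # gap state consuming target bases
    SE = np.zeros(m + 1, np.int64)
    best = 0
    best_start = np.int64(-1)
    best_end = np.int64(-1)
    open_cost = gap_open + gap_ext
    for i in range(1, n + 1):
        diag_h = H[0]
        diag_s = SH[0]
        F = NEG  # gap state consuming query bases, local to the row
        SF = np.int64(0)
        ti = t[i - 1]
        for j in range(1, m + 1):
            if ti == q[j - 1] and ti < 4:
                s = match
            else:
                s = mismatch
            # diagonal: extend the alignment ending at (i-1, j-1), or start fresh
            if diag_h > 0:
                cand = diag_h + s
                cand_s = diag_s
            else:
                cand = s
                cand_s = i - 1
            # E: gap consuming t[i-1] (from the row above, same column)
            e_open = H[j] - open_cost
            e_ext = E[j] - gap_ext
            if e_open >= e_ext:
                E[j] = e_open
                SE[j] = SH[j]
            else:
                E[j] = e_ext
            if E[j] > cand:
                cand = E[j]
                cand_s = SE[j]
            # F: gap consuming q[j-1] (from the left, same row; H[j-1] is row i)
            f_open = H[j - 1] - open_cost
            f_ext = F - gap_ext
            if f_open >= f_ext:
                F = f_open
                SF = SH[j - 1]
            else:
                F = f_ext
            if F > cand:
                cand = F
                cand_s = SF
            if cand < 0:
                cand = 0
                cand_s = i  # irrelevant; reset
            diag_h = H[j]
            diag_s = SH[j]
            H[j] = cand
            SH[j] = cand_s
            if cand > best or (cand == best and cand > 0 and cand_s < best_start):
                best = cand
                best_start = cand_s
                best_end = i
    if best <= 0:
        return np.int64(0), np.int64(-1), np.int64(-1)
    return np.int64(best), best_start, best_end
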