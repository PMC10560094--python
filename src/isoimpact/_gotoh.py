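"""Affine-gap global alignment kernel (Gotoh three-state dynamic program).

The kernel is generic over a precomputed column-score matrix, so the same
code aligns two sequences (scores = substitution-matrix lookups) and two
alignment profiles (scores = sum-of-pairs column scores). A gap of length L
costs gap_open + L * gap_extend, charged once per gap run.

Tie-breaking is fixed for determinism: at every maximization the match
state is preferred over a gap in the second operand ("up"), which is
preferred over a gap in the first ("left"); switching requires a strictly
better score.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# moves emitted by the traceback
DIAG = 0  # consume one column of A and one of B
UP = 1  # consume one column of A against a gap in B
LEFT = 2  # consume one column of B against a gap in A

_NEG = -1e30


@njit(cache=False)
def _gotoh_kernel(scores, gap_open, gap_extend):  # pragma: no cover - numba
    m, n = scores.shape
    M = np.full((m + 1, n + 1), _NEG)
    IX = np.full((m + 1, n + 1), _NEG)  # gap in B (vertical / "up")
    IY = np.full((m + 1, n + 1), _NEG)  # gap in A (horizontal / "left")
    # predecessor state per cell: 0 = M, 1 = IX, 2 = IY
    pM = np.zeros((m + 1, n + 1), dtype=np.int8)
    pX = np.zeros((m + 1, n + 1), dtype=np.int8)
    pY = np.zeros((m + 1, n + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, m + 1):
        IX[i, 0] = -(gap_open + i * gap_extend)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, n + 1):
        IY[0, j] = -(gap_open + j * gap_extend)
        pY[0, j] = 0 if j == 1 else 2

    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # match state: predecessor at (i-1, j-1), prefer M > IX > IY
            best = M[i - 1, j - 1]
            ptr = 0
            if IX[i - 1, j - 1] > best:
                best = IX[i - 1, j - 1]
                ptr = 1
            if IY[i - 1, j - 1] > best:
                best = IY[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + scores[i - 1, j - 1]
            pM[i, j] = ptr

            # gap in B: predecessor at (i-1, j)
            best = M[i - 1, j] - open_cost
            ptr = 0
            if IX[i - 1, j] - gap_extend > best:
                best = IX[i - 1, j] - gap_extend
                ptr = 1
            if IY[i - 1, j] - open_cost > best:
                best = IY[i - 1, j] - open_cost
                ptr = 2
            IX[i, j] = best
            pX[i, j] = ptr

            # gap in A: predecessor at (i, j-1)
            best = M[i, j - 1] - open_cost
            ptr = 0
            if IX[i, j - 1] - open_cost > best:
                best = IX[i, j - 1] - open_cost
                ptr = 1
            if IY[i, j - 1] - gap_extend > best:
                best = IY[i, j - 1] - gap_extend
                ptr = 2
            IY[i, j] = best
            pY[i, j] = ptr

    # final state: prefer M > IX > IY
    state = 0
    score = M[m, n]
    if IX[m, n] > score:
        score = IX[m, n]
        state = 1
    if IY[m, n] > score:
        score = IY[m, n]
        state = 2

    moves = np.empty(m + n, dtype=np.int8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:
            moves[k] = DIAG
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves[k] = UP
            state = pX[i, j]
            i -= 1
        else:
            moves[k] = LEFT
            state = pY[i, j]
            j -= 1
        k += 1
    return score, moves[:k][::-1].copy()


def gotoh_align(scores: np.ndarray, gap_open: float, gap_extend: float):
    """Optimal global alignment over a column-score matrix.

    Returns (score, moves) where moves is a 1-D array of DIAG/UP/LEFT steps
    from the start of both operands to their ends.
    """
    scores = np.ascontiguousarray(scores, dtype=np.float64)
    return _gotoh_kernel(scores, float(gap_open), float(gap_extend))
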