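"""Numba kernels for affine-gap dynamic programming (Gotoh three-state).

Both kernels operate on a precomputed position-score matrix ``smat`` of shape
(n, m): for sequence-sequence alignment this is a substitution-score lookup,
for profile-profile alignment it is the expected sum-of-pairs column score.
State codes: 0 = M (diagonal), 1 = X (gap in the second row, consumes a),
2 = Y (gap in the first row, consumes b).  Ties are always broken in the
order M > X > Y, which fixes the traceback deterministically (diagonal
preferred, then gap-in-b, then gap-in-a).

Gap convention: a gap of length L costs gap_open + (L - 1) * gap_extend.
"""

import numpy as np
from numba import njit

NEG = np.float32(-1e30)


@njit(cache=True)
def gotoh_global(smat, gap_open, gap_extend):
    n, m = smat.shape
    M = np.full((n + 1, m + 1), NEG, np.float32)
    X = np.full((n + 1, m + 1), NEG, np.float32)
    Y = np.full((n + 1, m + 1), NEG, np.float32)
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal move from the best of the three states
            a0 = M[i - 1, j - 1]
            a1 = X[i - 1, j - 1]
            a2 = Y[i - 1, j - 1]
            if a0 >= a1 and a0 >= a2:
                M[i, j] = a0 + smat[i - 1, j - 1]
                pM[i, j] = 0
            elif a1 >= a2:
                M[i, j] = a1 + smat[i - 1, j - 1]
                pM[i, j] = 1
            else:
                M[i, j] = a2 + smat[i - 1, j - 1]
                pM[i, j] = 2
            # X: consume a[i], gap in b
            b0 = M[i - 1, j] + gap_open
            b1 = X[i - 1, j] + gap_extend
            b2 = Y[i - 1, j] + gap_open
            if b0 >= b1 and b0 >= b2:
                X[i, j] = b0
                pX[i, j] = 0
            elif b1 >= b2:
                X[i, j] = b1
                pX[i, j] = 1
            else:
                X[i, j] = b2
                pX[i, j] = 2
            # Y: consume b[j], gap in a
            c0 = M[i, j - 1] + gap_open
            c1 = X[i, j - 1] + gap_open
            c2 = Y[i, j - 1] + gap_extend
            if c0 >= c1 and c0 >= c2:
                Y[i, j] = c0
                pY[i, j] = 0
            elif c1 >= c2:
                Y[i, j] = c1
                pY[i, j] = 1
            else:
                Y[i, j] = c2
                pY[i, j] = 2
    if M[n, m] >= X[n, m] and M[n, m] >= Y[n, m]:
        end_state = 0
        score = M[n, m]
    elif X[n, m] >= Y[n, m]:
        end_state = 1
        score = X[n, m]
    else:
        end_state = 2
        score = Y[n, m]
    return score, end_state, pM, pX, pY


# Predecessor code 3 in the local kernel marks the start of the alignment.
@njit(cache=True)
def gotoh_local(smat, gap_open, gap_extend):
    n, m = smat.shape
    M = np.full((n + 1, m + 1), NEG, np.float32)
    X = np.full((n + 1, m + 1), NEG, np.float32)
    Y = np.full((n + 1, m + 1), NEG, np.float32)
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    best = np.float32(0.0)
    bi = 0
    bj = 0
    bstate = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a0 = M[i - 1, j - 1]
            a1 = X[i - 1, j - 1]
            a2 = Y[i - 1, j - 1]
            zero = np.float32(0.0)
            if zero >= a0 and zero >= a1 and zero >= a2:
                M[i, j] = smat[i - 1, j - 1]
                pM[i, j] = 3
            elif a0 >= a1 and a0 >= a2:
                M[i, j] = a0 + smat[i - 1, j - 1]
                pM[i, j] = 0
            elif a1 >= a2:
                M[i, j] = a1 + smat[i - 1, j - 1]
                pM[i, j] = 1
            else:
                M[i, j] = a2 + smat[i - 1, j - 1]
                pM[i, j] = 2
            b0 = M[i - 1, j] + gap_open
            b1 = X[i - 1, j] + gap_extend
            b2 = Y[i - 1, j] + gap_open
            if b0 >= b1 and b0 >= b2:
                X[i, j] = b0
                pX[i, j] = 0
            elif b1 >= b2:
                X[i, j] = b1
                pX[i, j] = 1
            else:
                X[i, j] = b2
                pX[i, j] = 2
            c0 = M[i, j - 1] + gap_open
            c1 = X[i, j - 1] + gap_open
            c2 = Y[i, j - 1] + gap_extend
            if c0 >= c1 and c0 >= c2:
                Y[i, j] = c0
                pY[i, j] = 0
            elif c1 >= c2:
                Y[i, j] = c1
                pY[i, j] = 1
            else:
                Y[i, j] = c2
                pY[i, j] = 2
            # local maxima only ever end in a match column; gaps at the end
            # of a local alignment always lower the score
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
                bstate = 0
    return best, bi, bj, bstate, pM, pX, pY
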