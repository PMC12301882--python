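"""Affine-gap semi-global alignment of amplicon reads.

The read is aligned end-to-end; reference end gaps are free (the read may
cover any contiguous stretch of the amplicon). Scoring is match/mismatch with
affine gaps: a gap of length k costs ``gap_open + (k-1) * gap_extend``.

Traceback preference is deterministic (diagonal over deletion over insertion)
and extracted indels are subsequently left-normalized, so equal-score
alignments resolve to the leftmost placement — the usual normalization
convention for indel calling.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**7)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _dp_traceback(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = read.shape[0], ref.shape[0]
    M = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    X = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in read (deletion)
    Y = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in ref (insertion)
    pM = np.zeros((m + 1, n + 1), dtype=np.int8)
    pX = np.zeros((m + 1, n + 1), dtype=np.int8)
    pY = np.zeros((m + 1, n + 1), dtype=np.int8)

    for j in range(n + 1):
        M[0, j] = 0  # free leading reference gap
    for i in range(1, m + 1):
        Y[i, 0] = gap_open + (i - 1) * gap_extend
        pY[i, 0] = 2 if i > 1 else 0

    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            s = match if ri == ref[j - 1] and ri < 4 else mismatch
            # diagonal
            best, ptr = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, ptr = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, ptr = Y[i - 1, j - 1], 2
            M[i, j] = best + s
            pM[i, j] = ptr
            # deletion (consume ref)
            best, ptr = M[i, j - 1] + gap_open, 0
            if X[i, j - 1] + gap_extend > best:
                best, ptr = X[i, j - 1] + gap_extend, 1
            if Y[i, j - 1] + gap_open > best:
                best, ptr = Y[i, j - 1] + gap_open, 2
            X[i, j] = best
            pX[i, j] = ptr
            # insertion (consume read)
            best, ptr = M[i - 1, j] + gap_open, 0
            if X[i - 1, j] + gap_open > best:
                best, ptr = X[i - 1, j] + gap_open, 1
            if Y[i - 1, j] + gap_extend > best:
                best, ptr = Y[i - 1, j] + gap_extend, 2
            Y[i, j] = best
            pY[i, j] = ptr

    # free trailing reference gap: best over final row
    best_j, best_state, best = 0, 0, NEG
    for j in range(n + 1):
        for state in range(3):
            v = M[m, j] if state == 0 else (X[m, j] if state == 1 else Y[m, j])
            if v > best:
                best, best_j, best_state = v, j, state

    # traceback; ops: 0 = diagonal, 1 = deletion, 2 = insertion
    ops = np.empty(m + n + 2, dtype=np.int8)
    k = 0
    i, j, state = m, best_j, best_state
    while i > 0:
        if state == 0:
            ops[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = pX[i, j]
            j -= 1
        else:
            ops[k] = 2
            state = pY[i, j]
            i -= 1
        k += 1
    return ops[:k][::-1].copy(), j, best
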