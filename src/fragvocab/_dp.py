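"""Dynamic-programming kernels (numba-compiled).

Two alignment kernels over arbitrary real score matrices:

* :func:`sw_affine` — Smith-Waterman local alignment with affine gaps, used
  for profile-profile comparison.
* :func:`nw_semiglobal` — Needleman-Wunsch with free end gaps and a linear
  gap penalty, used for the structural aligner's re-pairing step.

Both kernels fill full DP matrices; tracebacks are done in Python by
recomputing cell recurrences (identical float arithmetic, deterministic tie
order: diagonal > vertical > horizontal).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def _sw_fill(S, gap_open, gap_ext):
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # vertical moves: gap in target
    F = np.full((n + 1, m + 1), NEG)  # horizontal moves: gap in query
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i - 1, j] - gap_open
            if E[i - 1, j] - gap_ext > e:
                e = E[i - 1, j] - gap_ext
            E[i, j] = e
            f = H[i, j - 1] - gap_open
            if F[i, j - 1] - gap_ext > f:
                f = F[i, j - 1] - gap_ext
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def sw_affine(S: np.ndarray, gap_open: float, gap_ext: float):
    """Local alignment over score matrix ``S`` (query rows, target cols).

    Returns ``(pairs, score)`` where ``pairs`` is a list of 0-based
    ``(query_index, target_index)`` tuples, strictly increasing in both
    coordinates, and ``score`` is the best local alignment score (>= 0).
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    go = float(gap_open)
    ge = float(gap_ext)
    H, E, F, best, i, j = _sw_fill(S, go, ge)
    pairs: list[tuple[int, int]] = []
    if best <= 0.0:
        return pairs, 0.0
    state = 0  # 0 = H, 1 = E (vertical), 2 = F (horizontal)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0.0:
                break
            if h == H[i - 1, j - 1] + S[i - 1, j - 1]:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = H[i - 1, j] - go
            e_next = 1 if E[i, j] != opened else 0
            i -= 1
            if not e_next:
                state = 0
        else:
            opened = H[i, j - 1] - go
            f_next = 1 if F[i, j] != opened else 0
            j -= 1
            if not f_next:
                state = 0
    pairs.reverse()
    return pairs, float(best)


@njit(cache=True)
def _nw_fill(S, gap):
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    # Free end gaps: first row and column stay at 0.
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j] - gap
            if up > h:
                h = up
            left = H[i, j - 1] - gap
            if left > h:
                h = left
            H[i, j] = h
    return H


def nw_semiglobal(S: np.ndarray, gap: float):
    """Global alignment with free end gaps and a linear gap penalty.

    Used to re-pair residues in structural alignment refinement, where ``S``
    is the proximity score matrix of the current superposition.  Returns the
    list of matched 0-based pairs on the best path.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    g = float(gap)
    H = _nw_fill(S, g)
    n, m = S.shape
    # Best cell on the last row or column (free terminal gaps).
    i, j = n, int(np.argmax(H[n, :]))
    if H[np.argmax(H[:, m]), m] > H[i, j]:
        i, j = int(np.argmax(H[:, m])), m
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + S[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif h == H[i - 1, j] - g:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs
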