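"""Independent brute-force oracles used by the tests.

These are deliberately naive implementations (full dynamic programming,
per-base scans) kept separate from the package so they can serve as
ground truth for the optimized code paths.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def semiglobal_affine_score(
    ref: str,
    read: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Optimal semi-global affine-gap score by full Gotoh DP.

    End gaps on the reference are free (the read may land anywhere inside
    the reference); the read must be consumed entirely. Gap cost model:
    the first gap base costs ``gap_open``, each further base ``gap_extend``.
    """
    m, n = len(ref), len(read)
    # M: ref i aligned to read j; Ix: gap in ref (read base consumed);
    # Iy: gap in read (ref base consumed)
    M = np.full((m + 1, n + 1), NEG)
    Ix = np.full((m + 1, n + 1), NEG)
    Iy = np.full((m + 1, n + 1), NEG)
    for i in range(m + 1):
        Iy[i][0] = 0.0  # leading reference overhang is free
    for j in range(1, n + 1):
        Ix[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(
                M[i][j - 1] + gap_open,
                Ix[i][j - 1] + gap_extend,
                Iy[i][j - 1] + gap_open,
            )
            internal_open = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_open)
            Iy[i][j] = max(internal_open, Iy[i - 1][j] + gap_extend)
    best = NEG
    for i in range(m + 1):
        best = max(best, M[i][n], Ix[i][n])
        if i == 0 or n == 0:
            best = max(best, Iy[i][n])
    return float(best)


def per_base_run_lengths(sequence: str) -> np.ndarray:
    """Length of the maximal homopolymer run containing each base."""
    n = len(sequence)
    out = np.zeros(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out
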