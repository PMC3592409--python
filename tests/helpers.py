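"""Independent oracles used to cross-check the implementation.

These are deliberately naive: an exhaustive window scan for clipping
and a full (unbanded) Gotoh dynamic program for local alignment.
They share no code with the package.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def clip_oracle(quals, window: int, min_avg_q: float):
    """Exhaustive scan over every window position.

    Returns (keep_start, keep_end, dropped) with the same contract as
    clip_read: the kept interval spans the outermost qualifying
    windows.
    """
    n = len(quals)
    qualifying = [
        i for i in range(n - window + 1)
        if sum(quals[i:i + window]) / window >= min_avg_q
    ]
    if not qualifying:
        return (0, 0, True)
    return (qualifying[0], qualifying[-1] + window, False)


def local_align_score_oracle(query: str, target: str, match: float,
                             mismatch: float, gap_open: float,
                             gap_extend: float) -> float:
    """Smith-Waterman/Gotoh optimal local score by full dynamic program.

    Gap of length L costs gap_open + (L-1)*gap_extend.
    """
    n, m = len(query), len(target)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if query[i - 1] == target[j - 1] else mismatch
            M[i, j] = max(0.0, M[i - 1, j - 1], Ix[i - 1, j - 1],
                          Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            best = max(best, M[i, j])
    return best
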