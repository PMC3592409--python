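"""Internal pairwise-alignment engine.

Affine-gap local alignment is delegated to Biopython's
``PairwiseAligner``.  For very large sequence pairs (contig vs. a long
reference) the dynamic program is replaced by edlib's banded
edit-distance alignment in infix mode, rescored under the configured
scheme; for the near-identical sequences this pipeline compares the
two routes agree.  Long references additionally use exact k-mer
seeding to restrict read placement to a candidate window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")

# Above this product of lengths, full affine DP is replaced by edlib.
FULL_DP_CELL_LIMIT = 100_000_000
# References longer than this use k-mer seeding for read placement.
SEEDED_REF_LEN = 20_000
SEED_K = 15


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores and acceptance thresholds.

    Gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    ``min_placement_score`` / ``min_identity`` gate whether a local
    alignment is accepted at all.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -3.0
    min_placement_score: float = 30.0
    min_identity: float = 0.80

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")


@dataclass
class LocalAlignment:
    """One local alignment of a query onto a target.

    ``pairs`` is the per-column correspondence: (target_pos, query_pos)
    with ``None`` on the gapped side; monotone in both coordinates.
    """

    score: float
    pairs: list[tuple[Optional[int], Optional[int]]]
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    identity: float


def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _pairs_from_blocks(t_blocks, q_blocks) -> list[tuple[Optional[int], Optional[int]]]:
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            pairs.extend((t, None) for t in range(prev_t, ts))
            pairs.extend((None, q) for q in range(prev_q, qs))
        pairs.extend(zip(range(ts, te), range(qs, qe)))
        prev_t, prev_q = te, qe
    return pairs


def _identity(pairs, target: str, query: str) -> float:
    if not pairs:
        return 0.0
    matches = sum(
        1 for t, q in pairs
        if t is not None and q is not None and target[t] == query[q]
    )
    return matches / len(pairs)


def _edlib_align(query: str, target: str,
                 scoring: ScoringScheme) -> Optional[LocalAlignment]:
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    t_start, t_end_incl = res["locations"][0]
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    t, q = t_start, 0
    num = ""
    score = 0.0
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            pairs.extend(zip(range(t, t + n), range(q, q + n)))
            score += n * (scoring.match if ch == "=" else scoring.mismatch)
            t += n
            q += n
        elif ch == "D":  # gap in query: target bases skipped
            pairs.extend((tp, None) for tp in range(t, t + n))
            score += scoring.gap_open + (n - 1) * scoring.gap_extend
            t += n
        elif ch == "I":  # gap in target: extra query bases
            pairs.extend((None, qp) for qp in range(q, q + n))
            score += scoring.gap_open + (n - 1) * scoring.gap_extend
            q += n
    return LocalAlignment(
        score=score,
        pairs=pairs,
        target_start=t_start,
        target_end=t_end_incl + 1,
        query_start=0,
        query_end=len(query),
        identity=_identity(pairs, target, query),
    )


def local_align(query: str, target: str,
                scoring: ScoringScheme) -> Optional[LocalAlignment]:
    """Best local alignment of ``query`` onto ``target``, or None.

    Returns None when the optimal local alignment is empty (score 0).
    Thresholding against ``min_placement_score`` / ``min_identity`` is
    the caller's concern.
    """
    if not query or not target:
        return None
    if len(query) * len(target) > FULL_DP_CELL_LIMIT:
        return _edlib_align(query, target, scoring)
    aligner = _aligner(scoring)
    score = aligner.score(target, query)
    if score <= 0:
        return None
    aln = aligner.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    pairs = _pairs_from_blocks(t_blocks, q_blocks)
    return LocalAlignment(
        score=float(aln.score),
        pairs=pairs,
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        identity=_identity(pairs, target, query),
    )


def build_kmer_index(seq: str, k: int = SEED_K) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


def seed_window(query: str, index: dict[str, list[int]], target_len: int,
                k: int = SEED_K, band: int = 60,
                pad: int = 120) -> Optional[tuple[int, int]]:
    """Candidate target window for ``query`` from exact k-mer seeds.

    Seeds are grouped by alignment diagonal (target - query position);
    the densest diagonal band wins.  Returns a (start, end) target
    interval, or None when no seed matches.
    """
    hits: list[tuple[int, int]] = []  # (diagonal, target_pos)
    step = max(1, k // 3)
    for q in range(0, len(query) - k + 1, step):
        for t in index.get(query[q:q + k], ()):
            hits.append((t - q, t))
    if not hits:
        return None
    hits.sort()
    best_count, best_lo, best_hi = 0, 0, 0
    i = 0
    for j in range(len(hits)):
        while hits[j][0] - hits[i][0] > band:
            i += 1
        if j - i + 1 > best_count:
            best_count = j - i + 1
            cluster = hits[i:j + 1]
            best_lo = min(t for _, t in cluster)
            best_hi = max(t for _, t in cluster)
    start = max(0, best_lo - len(query) - pad)
    end = min(target_len, best_hi + len(query) + pad)
    return start, end
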