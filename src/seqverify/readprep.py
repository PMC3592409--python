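"""Quality clipping of Sanger reads.

Read ends are trimmed by a windowed average-quality rule: the kept
interval runs from the first window of ``window`` consecutive bases
whose mean Phred score reaches ``min_avg_q`` to the last such window.
A read in which no window qualifies is dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import MAX_PHRED, Read


@dataclass(frozen=True)
class ClipPolicy:
    """Windowed average-quality clipping parameters."""

    window: int = 30
    min_avg_q: float = 20.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.min_avg_q <= MAX_PHRED:
            raise ValueError(f"min_avg_q must be in [0, {MAX_PHRED}]")


@dataclass
class ClippedRead:
    """A read plus the kept interval after end clipping.

    ``keep_start``/``keep_end`` are a 0-based half-open interval into
    the original read; ``dropped`` means no window qualified.
    """

    read: Read
    keep_start: int
    keep_end: int
    dropped: bool

    @property
    def bases(self) -> str:
        return self.read.bases[self.keep_start:self.keep_end]

    @property
    def quals(self) -> np.ndarray:
        return self.read.quals[self.keep_start:self.keep_end]

    def __len__(self) -> int:
        return self.keep_end - self.keep_start


def clip_read(read: Read, policy: ClipPolicy = ClipPolicy()) -> ClippedRead:
    """Clip low-quality ends; drop the read if no window qualifies.

    The kept interval starts at the smallest i with
    mean(quals[i:i+w]) >= q and ends at the largest j with
    mean(quals[j-w:j]) >= q.  Interior low-quality stretches between
    the two outermost qualifying windows are retained.
    """
    w = policy.window
    n = len(read)
    if n < w:
        return ClippedRead(read, 0, 0, dropped=True)
    csum = np.concatenate(([0], np.cumsum(read.quals, dtype=np.int64)))
    window_sums = csum[w:] - csum[:-w]  # sum over [i, i+w) for each i
    ok = np.flatnonzero(window_sums >= policy.min_avg_q * w)
    if ok.size == 0:
        return ClippedRead(read, 0, 0, dropped=True)
    keep_start = int(ok[0])
    keep_end = int(ok[-1]) + w
    return ClippedRead(read, keep_start, keep_end, dropped=False)


def clip_all(reads, policy: ClipPolicy = ClipPolicy()):
    """Clip every read; partition into (kept, dropped) preserving order.

    Dropped reads are carried forward so that a no-contig failure can
    be diagnosed as a sequencing failure rather than a clone failure.
    """
    kept, dropped = [], []
    for read in reads:
        clipped = clip_read(read, policy)
        (dropped if clipped.dropped else kept).append(clipped)
    return kept, dropped
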