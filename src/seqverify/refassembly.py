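"""Reference-guided (backbone) assembly with a reads-only consensus.

Clipped reads are placed individually on the reference by local
affine-gap alignment (both strands), stacked into a pileup, and a
consensus is called per column by quality-weighted voting.  The
backbone guides placement but contributes no observations: reference
positions covered by zero reads are never filled in, so coverage
holes split the consensus into multiple contigs.

Consensus rule per column: sum the Phred scores supporting each
candidate symbol (A/C/G/T/gap); the symbol with the highest summed
support wins, and when the top supports tie the call is the IUPAC
ambiguity code of the tied base set.  The consensus quality is the
winning support minus all conflicting support, clamped to [0, 90] —
so one Q50 read yields ~Q50 consensus, two agreeing reads add up, and
a disagreeing read subtracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._align import (SEEDED_REF_LEN, LocalAlignment, ScoringScheme,
                     build_kmer_index, local_align, revcomp, seed_window)
from .readprep import ClippedRead
from .seqio import ReferenceSeq

__all__ = [
    "ScoringScheme", "Placement", "PileupColumn", "Contig",
    "place_read", "place_reads", "build_pileup", "call_column",
    "consensus_from_pileup", "assemble", "contig_quality_profile",
    "write_pileup_tsv", "assembly_text_view",
]

MAX_CONSENSUS_Q = 90
GAP = "-"

_IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class Placement:
    """A read's local alignment onto the reference backbone.

    ``aligned_pairs`` holds (ref_pos, read_pos) per alignment column
    with ``None`` on the gapped side.  Read positions index into the
    *oriented* (strand-adjusted, clipped) sequence so that both
    coordinates are monotonically increasing; ``oriented_bases`` /
    ``oriented_quals`` carry that sequence in reference orientation.
    """

    read_id: str
    strand: str  # "+" or "-"
    ref_start: int
    ref_end: int
    aligned_pairs: list[tuple[Optional[int], Optional[int]]]
    score: float
    identity: float
    oriented_bases: str
    oriented_quals: np.ndarray

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)


@dataclass
class PileupColumn:
    """One multiple-alignment column over a reference coordinate.

    ``ins_idx`` 0 means the column sits on reference position
    ``ref_pos``; ``ins_idx`` k >= 1 is the k-th inserted column after
    it (``ref_base`` is then a gap).  Observations are
    (read_id, base-or-gap, phred) triples in reference orientation.
    """

    ref_pos: int
    ins_idx: int
    ref_base: str
    observations: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, int]:
        return (self.ref_pos, self.ins_idx)


@dataclass
class Contig:
    """Reads-only consensus over one contiguous covered reference run."""

    id: str
    bases: str
    quals: np.ndarray
    ref_span: tuple[int, int]  # 0-based half-open on the reference
    column_map: list[tuple[int, int]]  # contig position -> pileup column key

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int32)
        if len(self.bases) != len(self.quals):
            raise ValueError("contig bases/quals length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


def place_read(read: ClippedRead, reference: ReferenceSeq,
               scoring: ScoringScheme = ScoringScheme(),
               _kmer_index: Optional[dict] = None) -> Optional[Placement]:
    """Place one clipped read on the reference, trying both strands.

    Returns None when the best alignment falls below the score or
    identity thresholds (the read is then reported as unplaced, not a
    fatal error).  Equal strand scores resolve to "+".
    """
    if read.dropped:
        raise ValueError(f"read {read.read.id!r} was dropped by clipping")
    fwd = read.bases
    rev = revcomp(fwd)
    ref = reference.bases

    def try_strand(seq: str) -> Optional[LocalAlignment]:
        if len(ref) > SEEDED_REF_LEN:
            index = _kmer_index if _kmer_index is not None else build_kmer_index(ref)
            window = seed_window(seq, index, len(ref))
            if window is None:
                return None
            lo, hi = window
            aln = local_align(seq, ref[lo:hi], scoring)
            if aln is None:
                return None
            aln.pairs = [(None if t is None else t + lo, q) for t, q in aln.pairs]
            aln.target_start += lo
            aln.target_end += lo
            return aln
        return local_align(seq, ref, scoring)

    best = None
    for strand, seq in (("+", fwd), ("-", rev)):
        aln = try_strand(seq)
        if aln is not None and (best is None or aln.score > best[1].score):
            best = (strand, aln, seq)
    if best is None:
        return None
    strand, aln, seq = best
    if aln.score < scoring.min_placement_score or aln.identity < scoring.min_identity:
        return None
    quals = read.quals if strand == "+" else read.quals[::-1]
    return Placement(
        read_id=read.read.id,
        strand=strand,
        ref_start=aln.target_start,
        ref_end=aln.target_end,
        aligned_pairs=aln.pairs,
        score=aln.score,
        identity=aln.identity,
        oriented_bases=seq,
        oriented_quals=np.asarray(quals),
    )


def place_reads(reads: Sequence[ClippedRead], reference: ReferenceSeq,
                scoring: ScoringScheme = ScoringScheme()):
    """Place all kept reads; returns (placements, unplaced_read_ids)."""
    index = build_kmer_index(reference.bases) if len(reference) > SEEDED_REF_LEN else None
    placements, unplaced = [], []
    for read in reads:
        p = place_read(read, reference, scoring, _kmer_index=index)
        if p is None:
            unplaced.append(read.read.id)
        else:
            placements.append(p)
    return placements, unplaced


def build_pileup(placements: Sequence[Placement],
                 reference: ReferenceSeq) -> list[PileupColumn]:
    """Stack placements into sorted pileup columns.

    Deletion observations (a read gapped over a reference base) carry
    the minimum of the flanking read qualities.  Reads that span an
    insertion junction without inserting contribute an explicit gap
    observation to the insertion column, so insertions must outweigh
    the non-inserting coverage to reach the consensus.
    """
    columns: dict[tuple[int, int], PileupColumn] = {}
    ref = reference.bases

    def col(ref_pos: int, ins_idx: int) -> PileupColumn:
        key = (ref_pos, ins_idx)
        c = columns.get(key)
        if c is None:
            c = PileupColumn(ref_pos, ins_idx,
                             ref[ref_pos] if ins_idx == 0 else GAP)
            columns[key] = c
        return c

    # (placement, {ref_pos -> n inserted bases after it}) for the gap pass
    ins_by_placement: list[tuple[Placement, dict[int, int]]] = []
    for pl in placements:
        quals = pl.oriented_quals
        bases = pl.oriented_bases
        last_t: Optional[int] = None
        ins_count = 0
        inserts: dict[int, int] = {}
        pairs = pl.aligned_pairs
        for i, (t, q) in enumerate(pairs):
            if t is not None and q is not None:
                col(t, 0).observations.append((pl.read_id, bases[q], int(quals[q])))
                last_t = t
                ins_count = 0
            elif t is None:  # insertion in the read
                if last_t is None:
                    continue  # local alignments never start with a gap
                ins_count += 1
                inserts[last_t] = ins_count
                col(last_t, ins_count).observations.append(
                    (pl.read_id, bases[q], int(quals[q]))
                )
            else:  # deletion in the read: gap observation over ref base t
                prev_q = next_q = None
                for tt, qq in reversed(pairs[:i]):
                    if qq is not None:
                        prev_q = qq
                        break
                for tt, qq in pairs[i + 1:]:
                    if qq is not None:
                        next_q = qq
                        break
                flank = [int(quals[x]) for x in (prev_q, next_q) if x is not None]
                col(t, 0).observations.append(
                    (pl.read_id, GAP, min(flank) if flank else 0)
                )
                last_t = t
                ins_count = 0
        ins_by_placement.append((pl, inserts))

    # Non-inserting reads vote for "no insertion" at insertion columns.
    ins_keys = [k for k in columns if k[1] >= 1]
    if ins_keys:
        for pl, inserts in ins_by_placement:
            aligned_ref = {t: q for t, q in pl.aligned_pairs
                           if t is not None and q is not None}
            for (p, k) in ins_keys:
                if p in aligned_ref and (p + 1) in aligned_ref:
                    if inserts.get(p, 0) < k:
                        q_flank = min(int(pl.oriented_quals[aligned_ref[p]]),
                                      int(pl.oriented_quals[aligned_ref[p + 1]]))
                        columns[(p, k)].observations.append(
                            (pl.read_id, GAP, q_flank)
                        )
    return [columns[k] for k in sorted(columns)]


def call_column(col: PileupColumn, tie_margin: float = 0.0) -> tuple[str, int]:
    """Quality-weighted consensus call for one pileup column.

    Returns (IUPAC base or gap, consensus Phred).  The highest summed
    support wins; supports within ``tie_margin`` of the top are tied
    and yield an ambiguity code.  A gap tied with a base resolves to
    the base so the conflict surfaces as a discrepancy for review.
    The backbone is never an observation.
    """
    if not col.observations:
        raise ValueError(f"column {col.key} has no observations")
    support: dict[str, float] = {}
    for _, base, qual in col.observations:
        if base == "N":
            continue  # no-call carries no evidence
        support[base] = support.get(base, 0.0) + qual
    if not support:
        return ("N", 0)
    top = max(support.values())
    tied = {sym for sym, s in support.items() if s >= top - tie_margin}
    if GAP in tied and len(tied) > 1:
        tied.discard(GAP)
    if tied == {GAP}:
        winner = GAP
    else:
        winner = _IUPAC_FROM_SET[frozenset(tied)]
    # Everything that is not the single top support counts as conflict,
    # so an exact two-way tie cancels to quality 0.
    qual = int(np.clip(round(2 * top - sum(support.values())), 0, MAX_CONSENSUS_Q))
    return (winner, qual)


def consensus_from_pileup(columns: Sequence[PileupColumn],
                          tie_margin: float = 0.0,
                          id_prefix: str = "contig") -> list[Contig]:
    """Call every column and split the consensus at coverage holes.

    One contig per maximal run of contiguous covered reference
    positions; columns whose consensus is a gap are elided from the
    contig sequence (they remain visible in the pileup).
    """
    if not columns:
        return []
    runs: list[list[PileupColumn]] = [[]]
    prev_pos: Optional[int] = None
    for col in columns:
        if prev_pos is not None and col.ins_idx == 0 and col.ref_pos > prev_pos + 1:
            runs.append([])
        runs[-1].append(col)
        if col.ins_idx == 0:
            prev_pos = col.ref_pos
    contigs = []
    for i, run in enumerate(runs, start=1):
        bases, quals, cmap = [], [], []
        for col in run:
            base, qual = call_column(col, tie_margin)
            if base == GAP:
                continue
            bases.append(base)
            quals.append(qual)
            cmap.append(col.key)
        if not bases:
            continue
        span = (run[0].ref_pos, max(c.ref_pos for c in run) + 1)
        contigs.append(Contig(
            id=f"{id_prefix}_{i}",
            bases="".join(bases),
            quals=np.asarray(quals),
            ref_span=span,
            column_map=cmap,
        ))
    return contigs


def assemble(reads: Sequence[ClippedRead], reference: ReferenceSeq,
             scoring: ScoringScheme = ScoringScheme(),
             tie_margin: float = 0.0) -> list[Contig]:
    """Place reads, build the pileup and call consensus contigs.

    Zero contigs result exactly when zero reads could be placed.
    """
    placements, _ = place_reads(reads, reference, scoring)
    columns = build_pileup(placements, reference)
    return consensus_from_pileup(columns, tie_margin)


def contig_quality_profile(contig: Contig,
                           low_q: int = 20) -> tuple[float, list[int]]:
    """Mean consensus quality and 1-based positions below ``low_q``."""
    mean_q = float(np.mean(contig.quals)) if len(contig) else 0.0
    positions = [int(i) + 1 for i in np.flatnonzero(contig.quals < low_q)]
    return mean_q, positions


def write_pileup_tsv(columns: Sequence[PileupColumn], path,
                     tie_margin: float = 0.0) -> None:
    """Machine-readable pileup: one row per column with the consensus call."""
    with open(path, "w") as fh:
        fh.write("ref_pos\tins_idx\tref_base\tobservations\tconsensus\tqual\n")
        for col in columns:
            base, qual = call_column(col, tie_margin)
            obs = ",".join(f"{rid}:{b}:{q}" for rid, b, q in col.observations)
            fh.write(f"{col.ref_pos + 1}\t{col.ins_idx}\t{col.ref_base}\t"
                     f"{obs}\t{base}\t{qual}\n")


def assembly_text_view(columns: Sequence[PileupColumn],
                       placements: Sequence[Placement],
                       tie_margin: float = 0.0, width: int = 60) -> str:
    """Human-readable assembly view, one row per read plus reference
    and consensus, chunked to ``width`` columns per block."""
    fwd_ids = [p.read_id for p in placements if p.strand == "+"]
    rev_ids = [p.read_id for p in placements if p.strand == "-"]
    obs_rows: dict[str, list[str]] = {rid: [] for rid in fwd_ids + rev_ids}
    ref_row, cons_row, pos_row = [], [], []
    for col in columns:
        by_read = {rid: b for rid, b, _ in col.observations}
        for rid in obs_rows:
            obs_rows[rid].append(by_read.get(rid, " "))
        ref_row.append(col.ref_base)
        base, _ = call_column(col, tie_margin)
        cons_row.append(base)
        pos_row.append(col.ref_pos + 1 if col.ins_idx == 0 else None)
    blocks = []
    n = len(ref_row)
    label_w = max([len(r) for r in obs_rows] + [9]) + 2
    for start in range(0, n, width):
        end = min(n, start + width)
        first_pos = next((p for p in pos_row[start:end] if p is not None), "")
        lines = [f"# reference position {first_pos}"]
        for rid in fwd_ids:
            lines.append(f"{rid:<{label_w}}" + "".join(obs_rows[rid][start:end]))
        lines.append(f"{'reference':<{label_w}}" + "".join(ref_row[start:end]))
        for rid in rev_ids:
            lines.append(f"{rid:<{label_w}}" + "".join(obs_rows[rid][start:end]))
        lines.append(f"{'consensus':<{label_w}}" + "".join(cons_row[start:end]))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
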