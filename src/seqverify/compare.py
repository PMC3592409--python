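"""Contig-versus-reference comparison.

The consensus contig is aligned back to the reference; every
non-identical alignment column becomes a discrepancy (substitution,
insertion or deletion) reported in compact HGVS-like positional
notation ("254C>T", "599_600insT", "577delA").  The alignment
topology itself is classified (complete / partial / multiple / none)
because partial or multiple alignments flag assembly problems that a
clean discrepancy list would hide.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from ._align import LocalAlignment, ScoringScheme, local_align
from .refassembly import Contig
from .seqio import ReferenceSeq

MIN_SEGMENT_LEN = 30


@dataclass
class AlignmentSegment:
    """One local alignment of (part of) a contig onto the reference.

    Intervals are 0-based half-open; ``aligned_pairs`` are
    (ref_pos, contig_pos) in absolute contig coordinates.
    """

    contig_id: str
    ref_start: int
    ref_end: int
    contig_start: int
    contig_end: int
    score: float
    identity: float
    aligned_pairs: list[tuple[Optional[int], Optional[int]]]

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)

    @property
    def contig_interval(self) -> tuple[int, int]:
        return (self.contig_start, self.contig_end)


@dataclass
class Discrepancy:
    """One contig/reference difference in positional notation.

    ``ref_pos`` is 1-based; for insertions it is the left flanking
    reference position (the event sits between ref_pos and
    ref_pos + 1).  ``contig_qual`` is the consensus quality at the
    site (insertions: minimum over inserted bases; deletions: minimum
    flanking contig quality).
    """

    kind: str  # substitution | insertion | deletion
    ref_pos: int
    ref_allele: str
    contig_allele: str
    contig_qual: int

    @property
    def notation(self) -> str:
        if self.kind == "substitution":
            return f"{self.ref_pos}{self.ref_allele}>{self.contig_allele}"
        if self.kind == "insertion":
            return f"{self.ref_pos}_{self.ref_pos + 1}ins{self.contig_allele}"
        if len(self.ref_allele) == 1:
            return f"{self.ref_pos}del{self.ref_allele}"
        end = self.ref_pos + len(self.ref_allele) - 1
        return f"{self.ref_pos}_{end}del{self.ref_allele}"


_NOTATION_RE = re.compile(
    r"^(?:(?P<spos>\d+)(?P<ref>[A-Z])>(?P<alt>[A-Z])"
    r"|(?P<ipos>\d+)_(?P<ipos2>\d+)ins(?P<ins>[A-Z]+)"
    r"|(?P<dpos>\d+)(?:_(?P<dpos2>\d+))?del(?P<del>[A-Z]+))$"
)


def parse_notation(text: str) -> Discrepancy:
    """Parse "254C>T" / "599_600insT" / "577delA" / "577_579delACG"."""
    m = _NOTATION_RE.match(text)
    if not m:
        raise ValueError(f"unparseable discrepancy notation: {text!r}")
    if m.group("spos"):
        return Discrepancy("substitution", int(m.group("spos")),
                           m.group("ref"), m.group("alt"), 0)
    if m.group("ipos"):
        p, p2 = int(m.group("ipos")), int(m.group("ipos2"))
        if p2 != p + 1:
            raise ValueError(f"insertion anchors must be adjacent: {text!r}")
        return Discrepancy("insertion", p, "", m.group("ins"), 0)
    p = int(m.group("dpos"))
    deleted = m.group("del")
    if m.group("dpos2") and int(m.group("dpos2")) != p + len(deleted) - 1:
        raise ValueError(f"deletion span does not match alleles: {text!r}")
    return Discrepancy("deletion", p, deleted, "", 0)


@dataclass
class AlignmentClassification:
    """Topology of the contig/reference alignment."""

    category: str  # complete | partial | multiple | none
    covered_ref_fraction: float
    segment_count: int


def _segment_from(aln: LocalAlignment, contig_id: str,
                  contig_offset: int) -> AlignmentSegment:
    pairs = [(t, None if q is None else q + contig_offset) for t, q in aln.pairs]
    return AlignmentSegment(
        contig_id=contig_id,
        ref_start=aln.target_start,
        ref_end=aln.target_end,
        contig_start=aln.query_start + contig_offset,
        contig_end=aln.query_end + contig_offset,
        score=aln.score,
        identity=aln.identity,
        aligned_pairs=pairs,
    )


def align_contig(contig: Contig, reference: ReferenceSeq,
                 scoring: ScoringScheme = ScoringScheme(),
                 min_segment_len: int = MIN_SEGMENT_LEN) -> list[AlignmentSegment]:
    """Align a contig to the reference, allowing multiple segments.

    The best local alignment is taken first; the unaligned contig
    stretches on either side (if at least ``min_segment_len`` long)
    are then re-aligned against the full reference, iteratively, until
    no further segment clears the score and identity thresholds.
    Segments are returned sorted by contig position.
    """
    if not len(contig):
        raise ValueError("cannot align an empty contig")
    segments: list[AlignmentSegment] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < min_segment_len:
            return
        aln = local_align(contig.bases[lo:hi], reference.bases, scoring)
        if (aln is None or aln.score < scoring.min_placement_score
                or aln.identity < scoring.min_identity):
            return
        seg = _segment_from(aln, contig.id, lo)
        segments.append(seg)
        recurse(lo, seg.contig_start)
        recurse(seg.contig_end, hi)

    recurse(0, len(contig))
    return sorted(segments, key=lambda s: (s.contig_start, s.ref_start))


def _left_align_indel(kind: str, ref: str, pos0: int, alleles: str,
                      qual: int) -> Discrepancy:
    """Shift an indel to its leftmost equivalent placement.

    ``pos0`` is 0-based: for deletions the first deleted reference
    base, for insertions the reference base immediately left of the
    insertion point (-1 when inserting before the sequence start).
    """
    if kind == "deletion":
        seq = alleles
        while pos0 > 0 and ref[pos0 - 1] == seq[-1]:
            seq = ref[pos0 - 1] + seq[:-1]
            pos0 -= 1
        return Discrepancy("deletion", pos0 + 1, seq, "", qual)
    seq = alleles
    while pos0 >= 0 and ref[pos0] == seq[-1]:
        seq = ref[pos0] + seq[:-1]
        pos0 -= 1
    return Discrepancy("insertion", pos0 + 1, "", seq, qual)


def call_discrepancies(segment: AlignmentSegment, contig: Contig,
                       reference: ReferenceSeq) -> list[Discrepancy]:
    """Enumerate contig/reference differences within one segment.

    Adjacent inserted (or deleted) bases merge into one multi-base
    event; indels are left-aligned in repeat context so notation is
    deterministic.  An IUPAC ambiguity call that differs from the
    reference base counts as a substitution.
    """
    ref = reference.bases
    out: list[Discrepancy] = []
    pending_kind: Optional[str] = None
    pending_pos0 = 0
    pending_seq = ""
    pending_quals: list[int] = []
    last_t: Optional[int] = None
    last_q: Optional[int] = None

    def flush() -> None:
        nonlocal pending_kind, pending_seq, pending_quals
        if pending_kind is None:
            return
        qual = min(pending_quals) if pending_quals else 0
        out.append(_left_align_indel(pending_kind, ref, pending_pos0,
                                     pending_seq, qual))
        pending_kind = None
        pending_seq = ""
        pending_quals = []

    def flank_qual(q_left: Optional[int], q_right: Optional[int]) -> int:
        quals = [int(contig.quals[q]) for q in (q_left, q_right)
                 if q is not None and 0 <= q < len(contig)]
        return min(quals) if quals else 0

    pairs = segment.aligned_pairs
    for i, (t, q) in enumerate(pairs):
        if t is not None and q is not None:
            flush()
            if contig.bases[q] != ref[t]:
                out.append(Discrepancy("substitution", t + 1, ref[t],
                                       contig.bases[q],
                                       int(contig.quals[q])))
            last_t, last_q = t, q
        elif q is None:  # deletion: reference base absent from contig
            if pending_kind != "deletion":
                flush()
                pending_kind = "deletion"
                pending_pos0 = t
                next_q = next((qq for _, qq in pairs[i + 1:] if qq is not None),
                              None)
                pending_quals = [flank_qual(last_q, next_q)]
            pending_seq += ref[t]
            last_t = t
        else:  # insertion: contig base absent from reference
            if pending_kind != "insertion":
                flush()
                pending_kind = "insertion"
                pending_pos0 = last_t if last_t is not None else -1
                pending_quals = []
            pending_seq += contig.bases[q]
            pending_quals.append(int(contig.quals[q]))
            last_q = q
    flush()
    return out


def classify(segments: Sequence[AlignmentSegment],
             reference: ReferenceSeq) -> AlignmentClassification:
    """Classify alignment topology from segment reference intervals.

    complete = exactly one segment spanning the full reference;
    multiple = two or more segments; none = no segments; else partial.
    """
    n = len(segments)
    intervals = sorted(s.ref_interval for s in segments)
    covered = 0
    cur_start: Optional[int] = None
    cur_end = 0
    for start, end in intervals:
        if cur_start is None or start > cur_end:
            if cur_start is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        covered += cur_end - cur_start
    fraction = covered / len(reference)
    if n == 0:
        category = "none"
    elif n >= 2:
        category = "multiple"
    elif segments[0].ref_interval == (0, len(reference)):
        category = "complete"
    else:
        category = "partial"
    return AlignmentClassification(category, fraction, n)


def circular_diagnosis(segments: Sequence[AlignmentSegment],
                       reference: ReferenceSeq) -> bool:
    """Advisory flag for circular references.

    When sequencing a circular molecule, reads running past the
    reference origin typically produce two or three alignments; as
    long as one of them spans the entire reference the construct is
    probably fine.  The flag is advisory only — it never upgrades a
    verdict to Pass on its own.
    """
    if not reference.circular:
        return False
    if not 1 <= len(segments) <= 3:
        return False
    return any(s.ref_interval == (0, len(reference)) for s in segments)


def write_discrepancies_tsv(discrepancies: Sequence[Discrepancy], path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tnotation\tref_pos\tref_allele\tcontig_allele\tcontig_qual\n")
        for d in discrepancies:
            fh.write(f"{d.kind}\t{d.notation}\t{d.ref_pos}\t{d.ref_allele}\t"
                     f"{d.contig_allele}\t{d.contig_qual}\n")


def write_discrepancies_json(discrepancies: Sequence[Discrepancy], path) -> None:
    payload = [
        {"kind": d.kind, "notation": d.notation, "ref_pos": d.ref_pos,
         "ref_allele": d.ref_allele, "contig_allele": d.contig_allele,
         "contig_qual": d.contig_qual}
        for d in discrepancies
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_segments_bed(segments: Sequence[AlignmentSegment],
                       reference: ReferenceSeq, path) -> None:
    """Alignment segments as BED intervals in reference coordinates."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{reference.id}\t{s.ref_start}\t{s.ref_end}\t"
                     f"{s.contig_id}\t{int(s.score)}\t+\n")
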