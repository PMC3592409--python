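"""Verification verdicts and the Summary Report.

A clone Passes only when a single alignment spans the whole
reference with no discrepancies, the contig is no longer than the
reference and the average consensus quality exceeds 20.  A clone
Fails only when assembly produced no contig at all.  Everything else
is a Review, with a sub-reason naming the first failed requirement.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .compare import (AlignmentClassification, AlignmentSegment, Discrepancy,
                      align_contig, call_discrepancies, circular_diagnosis,
                      classify)
from .readprep import ClipPolicy, ClippedRead, clip_all
from .refassembly import (Contig, Placement, PileupColumn, ScoringScheme,
                          build_pileup, consensus_from_pileup,
                          contig_quality_profile, place_reads)
from .seqio import CloneJob, Read, ReferenceSeq

LOW_Q_THRESHOLD = 20
MIN_MEAN_Q = 20.0

# First failing requirement determines the Review sub-reason.
SUB_REASON_PRIORITY = (
    "No contig",
    "Discrepancies found",
    "Multiple alignments",
    "No alignment",
    "Partial alignment",
    "Contig longer than reference",
    "Low quality",
)


@dataclass(frozen=True)
class Status:
    """Verification verdict: Pass, Fail or Review plus a sub-reason."""

    value: str
    sub_reason: str = ""

    def __post_init__(self) -> None:
        if self.value not in ("Pass", "Fail", "Review"):
            raise ValueError(f"invalid status {self.value!r}")
        if self.value == "Pass" and self.sub_reason:
            raise ValueError("Pass carries no sub-reason")
        if self.value == "Fail" and self.sub_reason != "No contig":
            raise ValueError("Fail is reserved for 'No contig'")

    def __str__(self) -> str:
        return self.value if not self.sub_reason else f"{self.value} ({self.sub_reason})"


@dataclass
class VerificationResult:
    """Machine-readable twin of the Summary Report."""

    clone_name: str
    status: Status
    ref_length: int
    contig_found: bool
    contig_length: int = 0
    mean_contig_q: float = 0.0
    low_q_positions: dict[str, list[int]] = field(default_factory=dict)
    segments: list[AlignmentSegment] = field(default_factory=list)
    classification: Optional[AlignmentClassification] = None
    discrepancies: list[Discrepancy] = field(default_factory=list)
    dropped_reads: list[str] = field(default_factory=list)
    unplaced_reads: list[str] = field(default_factory=list)
    circular_flag: bool = False
    coverage_gaps: list[tuple[int, int, str]] = field(default_factory=list)


def determine_status(contig_found: bool, contig_length: int, ref_length: int,
                     n_discrepancies: int,
                     classification: Optional[AlignmentClassification],
                     mean_contig_q: float) -> Status:
    """Apply the Pass/Fail/Review decision rules.

    Pass requires: a contig no longer than the reference, zero
    discrepancies, a single alignment covering the entire reference
    and average consensus quality strictly above 20.  No contig at
    all is the only Fail.  Sub-reasons follow a fixed priority so
    reports are deterministic.
    """
    if not contig_found:
        return Status("Fail", "No contig")
    if n_discrepancies > 0:
        return Status("Review", "Discrepancies found")
    if classification is None or classification.segment_count == 0:
        return Status("Review", "No alignment")
    if classification.segment_count > 1:
        return Status("Review", "Multiple alignments")
    if classification.category != "complete":
        return Status("Review", "Partial alignment")
    if contig_length > ref_length:
        return Status("Review", "Contig longer than reference")
    if not mean_contig_q > MIN_MEAN_Q:
        return Status("Review", "Low quality")
    return Status("Pass")


def coverage_gaps(contigs: Sequence[Contig], reference: ReferenceSeq,
                  q_threshold: int = LOW_Q_THRESHOLD
                  ) -> list[tuple[int, int, str]]:
    """Reference intervals lacking confident consensus, 1-based inclusive.

    ``uncovered``: no contig base maps to the position;
    ``low_quality``: covered but consensus quality below threshold.
    """
    qual = np.full(len(reference), -1, dtype=np.int32)
    for contig in contigs:
        for pos, (ref_pos, ins_idx) in enumerate(contig.column_map):
            if ins_idx == 0:
                qual[ref_pos] = contig.quals[pos]
    gaps = []
    start = None
    label = ""
    for i in range(len(reference) + 1):
        state = None
        if i < len(reference):
            if qual[i] < 0:
                state = "uncovered"
            elif qual[i] < q_threshold:
                state = "low_quality"
        if state != label or i == len(reference):
            if start is not None and label:
                gaps.append((start + 1, i, label))
            start = i if state else None
            label = state or ""
    return gaps


def quality_profile(obj) -> list[tuple[int, int]]:
    """Per-position (1-based position, Phred) rows for plotting."""
    if isinstance(obj, (Read, Contig)):
        quals = obj.quals
    elif isinstance(obj, ClippedRead):
        quals = obj.read.quals
    else:
        quals = np.asarray(obj)
    return [(i + 1, int(q)) for i, q in enumerate(quals)]


def summarize(job: CloneJob, contigs: Sequence[Contig],
              segments: Sequence[AlignmentSegment],
              discrepancies: Sequence[Discrepancy],
              classification: Optional[AlignmentClassification],
              dropped_reads: Sequence[str] = (),
              unplaced_reads: Sequence[str] = (),
              circular_flag: bool = False) -> VerificationResult:
    """Assemble the full Summary Report content for one clone."""
    contig_found = len(contigs) > 0
    total_len = sum(len(c) for c in contigs)
    if total_len:
        mean_q = float(np.concatenate([c.quals for c in contigs]).mean())
    else:
        mean_q = 0.0
    low_q = {}
    for c in contigs:
        _, positions = contig_quality_profile(c, LOW_Q_THRESHOLD)
        if positions:
            low_q[c.id] = positions
    status = determine_status(contig_found, total_len, len(job.reference),
                              len(discrepancies), classification, mean_q)
    return VerificationResult(
        clone_name=job.clone_name,
        status=status,
        ref_length=len(job.reference),
        contig_found=contig_found,
        contig_length=total_len,
        mean_contig_q=mean_q,
        low_q_positions=low_q,
        segments=list(segments),
        classification=classification,
        discrepancies=list(discrepancies),
        dropped_reads=list(dropped_reads),
        unplaced_reads=list(unplaced_reads),
        circular_flag=circular_flag,
        coverage_gaps=coverage_gaps(contigs, job.reference),
    )


@dataclass
class CloneArtifacts:
    """Intermediate products kept for report writing and debugging."""

    kept_reads: list[ClippedRead]
    dropped_reads: list[ClippedRead]
    placements: list[Placement]
    pileup: list[PileupColumn]
    contigs: list[Contig]


def verify_clone(job: CloneJob,
                 clip_policy: ClipPolicy = ClipPolicy(),
                 scoring: ScoringScheme = ScoringScheme(),
                 tie_margin: float = 0.0
                 ) -> tuple[VerificationResult, CloneArtifacts]:
    """Run the whole verification pipeline for one clone.

    clip -> place -> pileup -> consensus -> contig/reference
    alignment -> discrepancies -> classification -> verdict.
    """
    kept, dropped = clip_all(job.reads, clip_policy)
    placements, unplaced = place_reads(kept, job.reference, scoring)
    pileup = build_pileup(placements, job.reference)
    contigs = consensus_from_pileup(pileup, tie_margin,
                                    id_prefix=f"{job.clone_name}_contig")
    segments: list[AlignmentSegment] = []
    discrepancies: list[Discrepancy] = []
    for contig in contigs:
        segs = align_contig(contig, job.reference, scoring)
        segments.extend(segs)
        for seg in segs:
            discrepancies.extend(call_discrepancies(seg, contig, job.reference))
    classification = classify(segments, job.reference) if contigs else None
    circ = circular_diagnosis(segments, job.reference)
    result = summarize(
        job, contigs, segments, discrepancies, classification,
        dropped_reads=[r.read.id for r in dropped],
        unplaced_reads=unplaced,
        circular_flag=circ,
    )
    return result, CloneArtifacts(kept, list(dropped), placements, pileup,
                                  list(contigs))


def result_to_dict(result: VerificationResult) -> dict:
    return {
        "schema_version": 1,
        "clone_name": result.clone_name,
        "status": result.status.value,
        "sub_reason": result.status.sub_reason,
        "ref_length": result.ref_length,
        "contig_found": result.contig_found,
        "contig_length": result.contig_length,
        "mean_contig_q": round(result.mean_contig_q, 2),
        "low_q_positions": result.low_q_positions,
        "segments": [
            {"contig_id": s.contig_id, "ref_start": s.ref_start,
             "ref_end": s.ref_end, "contig_start": s.contig_start,
             "contig_end": s.contig_end, "score": s.score,
             "identity": round(s.identity, 4)}
            for s in result.segments
        ],
        "classification": (
            None if result.classification is None else {
                "category": result.classification.category,
                "covered_ref_fraction":
                    round(result.classification.covered_ref_fraction, 4),
                "segment_count": result.classification.segment_count,
            }),
        "discrepancies": [
            {"kind": d.kind, "notation": d.notation, "ref_pos": d.ref_pos,
             "ref_allele": d.ref_allele, "contig_allele": d.contig_allele,
             "contig_qual": d.contig_qual}
            for d in result.discrepancies
        ],
        "dropped_reads": result.dropped_reads,
        "unplaced_reads": result.unplaced_reads,
        "circular_flag": result.circular_flag,
        "coverage_gaps": [
            {"start": a, "end": b, "label": label}
            for a, b, label in result.coverage_gaps
        ],
    }


def write_summary_json(result: VerificationResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result_to_dict(result), fh, indent=2, sort_keys=True)
        fh.write("\n")


def summary_text(result: VerificationResult) -> str:
    lines = [
        f"Clone:  {result.clone_name}",
        f"Status: {result.status}",
        "",
        f"Reference length: {result.ref_length}",
        f"Contig found:     {'yes' if result.contig_found else 'no'}",
    ]
    if result.contig_found:
        lines += [
            f"Contig length:    {result.contig_length}",
            f"Average quality:  {result.mean_contig_q:.1f}",
        ]
        if result.low_q_positions:
            for cid, positions in result.low_q_positions.items():
                lines.append(
                    f"Positions with quality < {LOW_Q_THRESHOLD} in {cid}: "
                    + ", ".join(map(str, positions))
                )
        else:
            lines.append(f"No positions with quality < {LOW_Q_THRESHOLD}.")
        lines.append("")
        if result.classification is not None:
            c = result.classification
            lines.append(
                f"Alignment: {c.category} "
                f"({c.segment_count} segment(s), "
                f"{100 * c.covered_ref_fraction:.1f}% of reference covered)"
            )
        for s in result.segments:
            lines.append(
                f"  {s.contig_id}: reference {s.ref_start + 1}-{s.ref_end}, "
                f"contig {s.contig_start + 1}-{s.contig_end}, "
                f"identity {100 * s.identity:.2f}%"
            )
        lines.append("")
        lines.append(f"Discrepancy check: {len(result.discrepancies)} found")
        for d in result.discrepancies:
            lines.append(f"  {d.notation}  (quality {d.contig_qual})")
        if result.coverage_gaps:
            lines.append("")
            lines.append("Coverage gaps (reference coordinates):")
            for a, b, label in result.coverage_gaps:
                lines.append(f"  {a}-{b}  {label}")
    if result.dropped_reads:
        lines.append("")
        lines.append("Reads dropped by quality clipping: "
                     + ", ".join(result.dropped_reads))
    if result.unplaced_reads:
        lines.append("Reads that could not be placed: "
                     + ", ".join(result.unplaced_reads))
    if result.circular_flag:
        lines.append("")
        lines.append("Circular reference: alignment pattern is consistent "
                     "with reads crossing the origin (manual review advised).")
    return "\n".join(lines) + "\n"


def write_summary_text(result: VerificationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(summary_text(result))


def write_rollup_csv(results: Sequence[VerificationResult], path) -> None:
    """Per-project roll-up: one row per clone."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["clone", "status", "sub_reason", "n_discrepancies",
                         "mean_q", "covered_fraction"])
        for r in results:
            covered = (0.0 if r.classification is None
                       else r.classification.covered_ref_fraction)
            writer.writerow([
                r.clone_name, r.status.value, r.status.sub_reason,
                len(r.discrepancies), f"{r.mean_contig_q:.2f}",
                f"{covered:.4f}",
            ])
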