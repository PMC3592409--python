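"""Synthetic Sanger-style sequencing data.

Generates random references, clone sequences carrying planted
variants, and reads with realistic quality profiles: a short
low-quality 5' ramp, a high-quality plateau over the usable span
(~850 bases), and a decaying 3' tail.  Base-call errors are injected
per position with probability 10^(-Q/10), matching the Phred
definition, so downstream quality arithmetic can be validated
against a known truth.

All randomness flows through explicit seeds into numpy PCG64
generators; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import (CloneJob, Read, ReferenceSeq, write_fasta, write_qual)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadProfile:
    """Quality-score profile along a simulated read.

    ``usable_span`` is where the high-quality plateau ends;
    ``tail_decay`` is Phred points lost per base past it.
    """

    usable_span: int = 850
    ramp_up: int = 25
    peak_q: int = 50
    start_q: int = 8
    tail_decay: float = 1.0
    noise_sd: float = 2.0
    read_length: int = 950

    def quality_curve(self, length: int, rng: np.random.Generator) -> np.ndarray:
        pos = np.arange(length, dtype=float)
        q = np.full(length, float(self.peak_q))
        if self.ramp_up > 0:
            ramp = pos < self.ramp_up
            q[ramp] = self.start_q + (self.peak_q - self.start_q) * (
                pos[ramp] / self.ramp_up)
        tail = pos >= self.usable_span
        q[tail] = self.peak_q - self.tail_decay * (pos[tail] - self.usable_span)
        if self.noise_sd > 0:
            q = q + rng.normal(0.0, self.noise_sd, size=length)
        return np.clip(np.rint(q), 0, 93).astype(np.int32)


@dataclass(frozen=True)
class Variant:
    """One planted edit relative to the reference.

    ``ref_pos`` is 1-based: the substituted/first deleted base, or
    the left flank of an insertion.
    """

    kind: str  # substitution | insertion | deletion
    ref_pos: int
    alleles: str  # new base(s) for sub/ins; deleted bases for del

    @property
    def notation(self) -> str:
        if self.kind == "insertion":
            return f"{self.ref_pos}_{self.ref_pos + 1}ins{self.alleles}"
        if self.kind == "deletion":
            if len(self.alleles) == 1:
                return f"{self.ref_pos}del{self.alleles}"
            return (f"{self.ref_pos}_{self.ref_pos + len(self.alleles) - 1}"
                    f"del{self.alleles}")
        return f"{self.ref_pos}{{ref}}>{self.alleles}"

    def span(self) -> tuple[int, int]:
        """Occupied 1-based reference interval, inclusive."""
        if self.kind == "deletion":
            return (self.ref_pos, self.ref_pos + len(self.alleles) - 1)
        return (self.ref_pos, self.ref_pos)


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def simulate_reference(length: int, gc: float = 0.5, seed: int = 0,
                       terminal_repeat: Optional[tuple[int, int]] = None,
                       ref_id: str = "reference") -> ReferenceSeq:
    """Random reference sequence, reproducible for a fixed seed.

    ``terminal_repeat=(k, d)`` replaces the final k bases with a copy
    of the first k bases carrying d mismatches — the inexact terminal
    repeat that produces multiple contig/reference alignments.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = list(_random_bases(length, gc, rng))
    if terminal_repeat is not None:
        k, d = terminal_repeat
        if k > length // 2:
            raise ValueError("terminal repeat longer than half the sequence")
        copy = list(seq[:k])
        for pos in rng.choice(k, size=min(d, k), replace=False):
            copy[pos] = rng.choice([b for b in "ACGT" if b != copy[pos]])
        seq[-k:] = copy
    return ReferenceSeq(ref_id, "".join(seq))


def mutate(reference: ReferenceSeq | str,
           variants: Sequence[Variant]) -> str:
    """Apply planted variants to a reference, right to left.

    Right-to-left application keeps every variant's 1-based reference
    position valid regardless of upstream indels.  Overlapping
    variants are rejected.
    """
    seq = reference.bases if isinstance(reference, ReferenceSeq) else reference
    spans = sorted(v.span() + (i,) for i, v in enumerate(variants))
    for (a_start, a_end, _), (b_start, b_end, _) in zip(spans, spans[1:]):
        if b_start <= a_end:
            raise ValueError(
                f"overlapping variants at positions {a_start} and {b_start}")
    out = seq
    for v in sorted(variants, key=lambda v: -v.ref_pos):
        i = v.ref_pos - 1
        if not 0 <= i < len(seq):
            raise ValueError(f"variant position {v.ref_pos} outside reference")
        if v.kind == "substitution":
            out = out[:i] + v.alleles + out[i + 1:]
        elif v.kind == "insertion":
            out = out[:i + 1] + v.alleles + out[i + 1:]
        elif v.kind == "deletion":
            if seq[i:i + len(v.alleles)] != v.alleles:
                raise ValueError(
                    f"deletion alleles {v.alleles!r} do not match reference "
                    f"at position {v.ref_pos}")
            out = out[:i] + out[i + len(v.alleles):]
        else:
            raise ValueError(f"unknown variant kind {v.kind!r}")
    return out


def random_variants(reference: ReferenceSeq, n: int, seed: int = 0,
                    margin: int = 80, min_spacing: int = 40
                    ) -> list[Variant]:
    """Plant n well-separated variants with unambiguous placement.

    Sites keep ``margin`` bases clear of both reference ends and
    ``min_spacing`` bases apart; indels are chosen so they cannot be
    left-shifted, making the planted notation the canonical one.
    """
    rng = np.random.default_rng(seed)
    seq = reference.bases
    variants: list[Variant] = []
    taken: list[int] = []
    attempts = 0
    while len(variants) < n and attempts < 2000:
        attempts += 1
        pos = int(rng.integers(margin, len(seq) - margin))  # 1-based
        if any(abs(pos - t) < min_spacing for t in taken):
            continue
        kind = ["substitution", "insertion", "deletion"][int(rng.integers(3))]
        i = pos - 1
        if kind == "substitution":
            alt = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
            variants.append(Variant("substitution", pos, alt))
        elif kind == "insertion":
            # not left-shiftable: inserted base differs from left flank
            ins = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
            variants.append(Variant("insertion", pos, ins))
        else:
            # not left-shiftable: deleted base differs from left flank
            if seq[i] == seq[i - 1]:
                continue
            variants.append(Variant("deletion", pos, seq[i]))
        taken.append(pos)
    if len(variants) < n:
        raise ValueError("could not place the requested variants")
    return sorted(variants, key=lambda v: v.ref_pos)


def _corrupt(bases: str, quals: np.ndarray, rng: np.random.Generator,
             indel_rate: float = 0.0) -> tuple[str, np.ndarray]:
    """Miscall each base with probability 10^(-Q/10); optional indels."""
    arr = np.array(list(bases))
    p_err = np.power(10.0, -quals / 10.0)
    miscall = rng.random(len(arr)) < p_err
    for i in np.flatnonzero(miscall):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    if indel_rate <= 0:
        return "".join(arr), quals
    out_b: list[str] = []
    out_q: list[int] = []
    for i in range(len(arr)):
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion error
        out_b.append(arr[i])
        out_q.append(int(quals[i]))
        if r >= indel_rate / 2 and r < indel_rate:
            out_b.append(str(rng.choice(BASES)))
            out_q.append(int(quals[i]))
    return "".join(out_b), np.asarray(out_q, dtype=np.int32)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reads(template: str,
                   primers: Sequence[tuple[int, str]],
                   profile: ReadProfile = ReadProfile(),
                   seed: int = 0,
                   indel_rate: float = 0.0,
                   id_prefix: str = "read") -> list[Read]:
    """Simulate one read per primer on a linear template.

    A primer is (0-based template position, strand).  A "+" read runs
    rightward from its start; a "-" read runs leftward and is emitted
    as the reverse complement, exactly as a sequencer would report it.
    The quality curve follows the read's own 5'->3' direction.
    """
    rng = np.random.default_rng(seed)
    reads = []
    for idx, (start, strand) in enumerate(primers):
        if not 0 <= start < len(template):
            raise ValueError(f"primer start {start} outside template")
        if strand == "+":
            raw = template[start:start + profile.read_length]
        elif strand == "-":
            lo = max(0, start - profile.read_length + 1)
            raw = _revcomp(template[lo:start + 1])
        else:
            raise ValueError(f"invalid strand {strand!r}")
        quals = profile.quality_curve(len(raw), rng)
        bases, quals = _corrupt(raw, quals, rng, indel_rate)
        reads.append(Read(f"{id_prefix}_{idx + 1:02d}_{strand}", bases, quals))
    return reads


def simulate_read_pair(clone_seq: str,
                       profile: ReadProfile = ReadProfile(),
                       seed: int = 0,
                       flank: int = 60,
                       indel_rate: float = 0.0,
                       id_prefix: str = "read") -> list[Read]:
    """Forward/reverse read pair for a gene-sized clone.

    Sequencing primers sit in vector sequence flanking the insert, so
    the template is the clone plus random flanks; quality clipping
    then removes read starts inside the flank, leaving the insert
    itself covered at high quality.
    """
    rng = np.random.default_rng(seed)
    template = (_random_bases(flank, 0.5, rng) + clone_seq
                + _random_bases(flank, 0.5, rng))
    sub_seeds = rng.integers(0, 2**31 - 1, size=2)
    fwd = simulate_reads(template, [(0, "+")], profile, int(sub_seeds[0]),
                         indel_rate, id_prefix=f"{id_prefix}_F")
    rev = simulate_reads(template, [(len(template) - 1, "-")], profile,
                         int(sub_seeds[1]), indel_rate,
                         id_prefix=f"{id_prefix}_R")
    return fwd + rev


def simulate_primer_walk(clone_seq: str, n_primers: int,
                         profile: ReadProfile = ReadProfile(),
                         seed: int = 0, flank: int = 60,
                         indel_rate: float = 0.0,
                         id_prefix: str = "read") -> list[Read]:
    """Primer-walk sequencing of a long clone with vector flanks.

    As with the read-pair mode, primers near the construct ends sit
    in flanking vector sequence, so after quality clipping the clone
    itself stays covered end to end.
    """
    rng = np.random.default_rng(seed)
    template = (_random_bases(flank, 0.5, rng) + clone_seq
                + _random_bases(flank, 0.5, rng))
    primers = primer_walk(len(template), n_primers, profile.read_length)
    return simulate_reads(template, primers, profile,
                          int(rng.integers(0, 2**31 - 1)), indel_rate,
                          id_prefix)


def primer_walk(template_len: int, n_primers: int,
                read_length: int = 950) -> list[tuple[int, str]]:
    """Evenly spaced primers on alternating strands covering a template."""
    primers = []
    step = max(1, template_len // n_primers)
    for i in range(n_primers):
        if i % 2 == 0:
            primers.append((min(i * step, template_len - 1), "+"))
        else:
            primers.append((min(i * step + read_length, template_len - 1), "-"))
    return primers


def simulate_project(out_dir, n_clones: int = 3, ref_length: int = 900,
                     n_variants: int = 0, seed: int = 0,
                     profile: ReadProfile = ReadProfile(),
                     variants: Optional[Sequence[Variant]] = None
                     ) -> tuple[list[CloneJob], dict[str, list[str]]]:
    """Write a ready-to-verify project (FASTA + QUAL + mapping CSV).

    Returns the in-memory jobs and, per clone, the list of planted
    variant notations (the ground truth).
    """
    out_dir = Path(out_dir)
    (out_dir / "refs").mkdir(parents=True, exist_ok=True)
    (out_dir / "reads").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    jobs = []
    truth: dict[str, list[str]] = {}
    mapping_rows = []
    for c in range(n_clones):
        name = f"clone{c + 1:03d}"
        ref_seed = int(rng.integers(0, 2**31 - 1))
        reference = simulate_reference(ref_length, seed=ref_seed,
                                       ref_id=f"{name}_ref")
        if variants is not None:
            reference, planted = _constrain_reference(reference, variants)
        elif n_variants > 0:
            planted = random_variants(reference, n_variants,
                                      seed=int(rng.integers(0, 2**31 - 1)))
        else:
            planted = []
        clone_seq = mutate(reference, planted)
        reads = simulate_read_pair(clone_seq, profile,
                                   seed=int(rng.integers(0, 2**31 - 1)),
                                   id_prefix=name)
        ref_file = f"{name}_ref.fasta"
        write_fasta([(reference.id, reference.bases)], out_dir / "refs" / ref_file)
        read_file = f"{name}_reads.fasta"
        write_fasta([(r.id, r.bases) for r in reads],
                    out_dir / "reads" / read_file)
        write_qual([(r.id, r.quals) for r in reads],
                   out_dir / "reads" / f"{name}_reads.qual")
        mapping_rows.append(f"{name},{ref_file},{read_file}")
        jobs.append(CloneJob(name, reference, reads))
        truth[name] = [_resolved_notation(reference, v) for v in planted]
    (out_dir / "mapping.csv").write_text("\n".join(mapping_rows) + "\n")
    return jobs, truth


def _constrain_reference(reference: ReferenceSeq,
                         variants: Sequence[Variant]
                         ) -> tuple[ReferenceSeq, list[Variant]]:
    """Adjust a random reference so explicit variants are well-posed.

    A substitution must change the base; an indel must not be
    left-shiftable (otherwise the planted notation would not be the
    canonical left-aligned one).  Deletion alleles are taken from the
    (adjusted) reference.
    """
    seq = list(reference.bases)

    def other(*exclude: str) -> str:
        return next(b for b in "ACGT" if b not in exclude)

    for v in variants:
        i = v.ref_pos - 1
        if not 0 <= i < len(seq):
            raise ValueError(f"variant position {v.ref_pos} outside reference")
        if v.kind == "substitution" and seq[i] == v.alleles:
            seq[i] = other(v.alleles)
        elif v.kind == "insertion" and seq[i] == v.alleles[-1]:
            seq[i] = other(v.alleles[-1], seq[i])
        elif v.kind == "deletion":
            last = i + len(v.alleles) - 1
            if i > 0 and seq[i - 1] == seq[last]:
                seq[i - 1] = other(seq[last], seq[i - 1])
    adjusted = ReferenceSeq(reference.id, "".join(seq))
    planted = [
        v if v.kind != "deletion" else Variant(
            "deletion", v.ref_pos,
            adjusted.bases[v.ref_pos - 1:v.ref_pos - 1 + len(v.alleles)])
        for v in variants
    ]
    return adjusted, planted


def _resolved_notation(reference: ReferenceSeq, v: Variant) -> str:
    if v.kind == "substitution":
        return f"{v.ref_pos}{reference.bases[v.ref_pos - 1]}>{v.alleles}"
    return v.notation
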