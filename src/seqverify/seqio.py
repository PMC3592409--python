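"""Input/output of sequencing data and project descriptions.

Reads arrive as FASTA base calls plus a parallel QUAL file of Phred
scores (or, equivalently, FASTQ).  Reference sequences are plain FASTA.
A batch ("project") is described by a three-column mapping table with
one row per read: clone name, reference file, read file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MAX_PHRED = 93

# Full IUPAC nucleotide alphabet accepted in read FASTA input.
IUPAC_CHARS = frozenset("ACGTUNRYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass
class Read:
    """A base-called sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    quals: np.ndarray
    source_file: str = ""

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int32)
        if not self.id:
            raise ValueError("read id must be non-empty")
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            raise ValueError(
                f"read {self.id!r}: quality scores must be in [0, {MAX_PHRED}]"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReferenceSeq:
    """The expected (designed) sequence of a clone."""

    id: str
    bases: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.bases) - set("ACGT")
        if bad:
            raise ValueError(
                f"reference {self.id!r} contains ambiguity or non-DNA "
                f"characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class CloneJob:
    """One clone to verify: its reference plus all its reads."""

    clone_name: str
    reference: ReferenceSeq
    reads: list[Read]

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError(f"clone {self.clone_name!r} has no reads")


@dataclass
class CloneJobSpec:
    """Unresolved mapping-file entry: file names, not loaded data."""

    clone_name: str
    reference_file: str
    read_files: list[str] = field(default_factory=list)


def _normalize_bases(raw: str, record_id: str, path: str) -> str:
    bases = "".join(raw.split()).upper().replace("U", "T")
    for pos, ch in enumerate(bases):
        if ch not in IUPAC_CHARS:
            raise FormatError(
                f"{path}: record {record_id!r} has invalid character "
                f"{ch!r} at position {pos + 1}"
            )
    return bases


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``[(id, bases), ...]`` in file order.

    Bases are upper-cased and U is mapped to T.  Empty files and
    duplicate record ids are format errors.
    """
    path = str(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, _normalize_bases(str(rec.seq), rec.id, path)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(bases), id=rid, description="") for rid, bases in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_qual(path) -> list[tuple[str, list[int]]]:
    """Parse a QUAL file into ``[(id, [phred, ...]), ...]``.

    Multi-line score blocks are concatenated.  Scores outside
    [0, 93] and non-integer tokens are format errors.
    """
    path = str(path)
    import warnings

    from Bio import BiopythonParserWarning

    try:
        with warnings.catch_warnings():
            # Biopython silently clamps negative scores to zero; treat
            # them as the format violation they are.
            warnings.simplefilter("error", BiopythonParserWarning)
            parsed = [
                (rec.id, list(rec.letter_annotations["phred_quality"]))
                for rec in SeqIO.parse(path, "qual")
            ]
    except (ValueError, BiopythonParserWarning) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: no QUAL records found")
    out = []
    seen: set[str] = set()
    for rid, quals in parsed:
        if rid in seen:
            raise FormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        for q in quals:
            if q < 0 or q > MAX_PHRED:
                raise FormatError(
                    f"{path}: record {rid!r} has quality score {q} "
                    f"outside [0, {MAX_PHRED}]"
                )
        out.append((rid, quals))
    return out


def write_qual(records: Iterable[tuple[str, Sequence[int]]], path,
               per_line: int = 20) -> None:
    with open(path, "w") as fh:
        for rid, quals in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(quals), per_line):
                fh.write(" ".join(str(int(q)) for q in quals[i:i + per_line]))
                fh.write("\n")


def pair_reads(fasta_records: Sequence[tuple[str, str]],
               qual_records: Sequence[tuple[str, Sequence[int]]],
               source_file: str = "") -> list[Read]:
    """Match FASTA and QUAL records by id into :class:`Read` objects.

    Every id must appear in both inputs with equal lengths; orphans on
    either side and length mismatches are format errors.
    """
    qual_by_id = {rid: q for rid, q in qual_records}
    fasta_ids = {rid for rid, _ in fasta_records}
    orphans = sorted(fasta_ids ^ set(qual_by_id))
    if orphans:
        raise FormatError(
            "records present in only one of the FASTA/QUAL inputs: "
            + ", ".join(orphans)
        )
    reads = []
    for rid, bases in fasta_records:
        quals = qual_by_id[rid]
        if len(bases) != len(quals):
            raise FormatError(
                f"record {rid!r}: {len(bases)} bases but {len(quals)} "
                "quality scores"
            )
        reads.append(Read(rid, bases, np.asarray(quals), source_file))
    return reads


def read_fastq(path) -> list[Read]:
    """Read FASTQ (Sanger / Phred+33 offset) as an alternative to FASTA+QUAL."""
    path = str(path)
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        bases = _normalize_bases(str(rec.seq), rec.id, path)
        quals = np.asarray(rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, bases, quals, path))
    if not reads:
        raise FormatError(f"{path}: no FASTQ records found")
    return reads


def _mapping_rows(path: str) -> list[tuple[str, str, str]]:
    if path.endswith(".xlsx"):
        try:
            from openpyxl import load_workbook
        except ImportError as exc:  # pragma: no cover - optional extra
            raise FormatError(
                f"{path}: xlsx mapping files require the 'openpyxl' package"
            ) from exc
        ws = load_workbook(path, read_only=True).active
        raw = [tuple("" if c is None else str(c).strip() for c in row[:3])
               for row in ws.iter_rows(values_only=True)]
    else:
        with open(path, newline="") as fh:
            text = fh.read()
        delim = "\t" if ("\t" in text and "," not in text.splitlines()[0]) else ","
        raw = [tuple(cell.strip() for cell in row[:3])
               for row in csv.reader(text.splitlines(), delimiter=delim)]
    rows = []
    for i, row in enumerate(raw, start=1):
        if not any(row):
            continue
        if len(row) < 3 or not all(row[:3]):
            raise FormatError(
                f"{path}: row {i} does not have three non-empty columns"
            )
        rows.append((row[0], row[1], row[2]))
    return rows


def read_mapping_file(path) -> list[CloneJobSpec]:
    """Parse a clone/reference/read mapping table (CSV, TSV or xlsx).

    One row per read, no header; rows with the same clone name are
    grouped.  A clone listed with two different reference files is an
    error.
    """
    path = str(path)
    rows = _mapping_rows(path)
    if not rows:
        raise FormatError(f"{path}: mapping file is empty")
    jobs: dict[str, CloneJobSpec] = {}
    for clone, ref_file, read_file in rows:
        spec = jobs.get(clone)
        if spec is None:
            jobs[clone] = CloneJobSpec(clone, ref_file, [read_file])
        else:
            if spec.reference_file != ref_file:
                raise FormatError(
                    f"{path}: clone {clone!r} is mapped to two different "
                    f"reference files: {spec.reference_file!r} and {ref_file!r}"
                )
            if read_file not in spec.read_files:
                spec.read_files.append(read_file)
    return list(jobs.values())


def load_clone_jobs(specs: Sequence[CloneJobSpec], ref_dir, read_dir) -> list[CloneJob]:
    """Resolve mapping-file entries against directories of data files.

    Read files may be FASTA (with a sibling ``.qual`` file) or FASTQ.
    All missing files across all clones are reported in one error.
    """
    ref_dir, read_dir = Path(ref_dir), Path(read_dir)
    missing = []
    for spec in specs:
        if not (ref_dir / spec.reference_file).exists():
            missing.append(str(ref_dir / spec.reference_file))
        for rf in spec.read_files:
            p = read_dir / rf
            if not p.exists():
                missing.append(str(p))
            elif p.suffix.lower() not in {".fastq", ".fq"}:
                qp = p.with_suffix(".qual")
                if not qp.exists():
                    missing.append(str(qp))
    if missing:
        raise FormatError("missing input files: " + ", ".join(missing))

    jobs = []
    for spec in specs:
        ref_records = read_fasta(ref_dir / spec.reference_file)
        rid, bases = ref_records[0]
        reference = ReferenceSeq(rid, bases)
        reads: list[Read] = []
        for rf in spec.read_files:
            p = read_dir / rf
            if p.suffix.lower() in {".fastq", ".fq"}:
                reads.extend(read_fastq(p))
            else:
                reads.extend(
                    pair_reads(read_fasta(p), read_qual(p.with_suffix(".qual")),
                               source_file=str(p))
                )
        jobs.append(CloneJob(spec.clone_name, reference, reads))
    return jobs
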