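# seqverify

Sequence verification of clones, plasmids and synthetic DNA constructs
from Sanger sequencing reads.

Gene synthesis, ORFeome collections and routine molecular cloning all
end with the same question: does the physical sequence of a clone match
its designed (reference) sequence?  Answering it by eyeballing
chromatograms is slow and error-prone.  `seqverify` automates the
analysis in two steps:

1. **Assembly.**  Base-called reads (FASTA + QUAL Phred scores, or
   FASTQ) are quality-clipped, placed on the reference *backbone* by
   local affine-gap alignment on both strands, and stacked into a
   pileup.  A **reads-only consensus contig** is called per column by
   quality-weighted voting — the backbone guides placement but never
   contributes a base, so uncovered reference regions stay uncovered
   instead of being silently filled in.
2. **Comparison.**  The contig is aligned back to the reference; every
   difference is reported as a substitution, insertion or deletion in
   compact positional notation (`254C>T`, `599_600insT`, `577delA`),
   together with the consensus quality at the site.  The alignment
   topology (complete / partial / multiple) is classified because a
   fragmented alignment flags problems a clean discrepancy list would
   hide.

Each clone receives a verdict:

| Status | Meaning |
| --- | --- |
| **Pass**   | one alignment spanning the whole reference, zero discrepancies, contig not longer than the reference, mean consensus quality > 20 |
| **Fail**   | no contig could be assembled at all (often a sequencing failure, not a clone failure — per-read diagnostics are reported) |
| **Review** | anything else, with a sub-reason: discrepancies found, multiple alignments, partial alignment, contig longer than reference, low quality |

## The consensus model

Each read base contributes its Phred score
(Q = −10·log₁₀ P(error)) as a vote for its base (or for a gap).  Per
pileup column, the symbol with the highest summed support wins; the
consensus quality is the winning support minus all conflicting
support, clamped to [0, 90].  One Q50 read in agreement gives a ~Q50
consensus; two agreeing reads push it into the 80s–90s; a conflicting
read subtracts.  When the top supports tie exactly, the call is the
IUPAC ambiguity code of the tied bases (e.g. `R` for A/G) at quality
0, so unresolvable conflicts are surfaced rather than guessed.

Reads are end-clipped by the windowed rule "minimum average quality
20 over 30 consecutive bases": the kept interval spans the outermost
qualifying windows, and a read with no qualifying window is dropped.

## Worked example

Simulate a clone whose physical sequence differs from its 900 bp
reference by one substitution and one insertion, then verify it:

```bash
seqverify simulate --out demo --variants "254C>T,599_600insT" --seed 42
seqverify verify-clone --name clone001 \
    --reference demo/refs/clone001_ref.fasta \
    --reads demo/reads/clone001_reads.fasta --out demo_out
```

prints `clone001	Review (Discrepancies found)` and writes
`demo_out/summary.txt`:

```
Clone:  clone001
Status: Review (Discrepancies found)

Reference length: 900
Contig found:     yes
Contig length:    901
Average quality:  82.8
No positions with quality < 20.

Alignment: complete (1 segment(s), 100.0% of reference covered)
  clone001_contig_1: reference 1-900, contig 1-901, identity 99.78%

Discrepancy check: 2 found
  254G>T  (quality 90)
  599_600insT  (quality 90)
```

Both planted variants are recovered at their planted positions, with
quality 90 (both strands agree), and the clone is routed to Review —
a discrepancy is a biological finding for a scientist to judge, not a
program error.  The output directory also contains `summary.json`
(machine-readable), the consensus as `contigs.fasta`/`contigs.qual`,
a per-column `pileup.tsv` and a human-readable `assembly.txt` view.

Batches are verified with `seqverify verify-project --mapping
mapping.csv --refs refs/ --reads reads/ --out out/`, where the
mapping file has one row per read (clone name, reference file, read
file, no header); one clone's failure never aborts the batch, and a
roll-up CSV summarises every clone.

## Library use

```python
from seqverify import CloneJob, verify_clone
from seqverify.simdata import simulate_reference, simulate_read_pair

ref = simulate_reference(900, seed=11)
reads = simulate_read_pair(ref.bases, seed=3)
result, artifacts = verify_clone(CloneJob("c1", ref, reads))
print(result.status)            # Pass
print(result.mean_contig_q)     # ~83 with two agreeing reads
```

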