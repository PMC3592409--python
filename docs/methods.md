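# Methods

## Pipeline overview

Verification of a clone proceeds in five stages: quality clipping of
the base-called reads, placement of each read on the reference
backbone, pileup construction, reads-only consensus calling, and
comparison of the consensus contig against the reference.  The final
verdict is a pure function of the comparison outputs.

## Quality clipping

Reads are trimmed by a windowed average-quality rule with window
length 30 bases and threshold Q20 (both configurable).  The kept
interval runs from the first window whose arithmetic mean Phred score
reaches the threshold to the last such window; a read with no
qualifying window anywhere is dropped entirely.  Consequences of this
definition:

- the mean is taken over raw Phred scores, not error probabilities —
  matching common clipping practice for Sanger data;
- interior low-quality stretches *between* the outermost qualifying
  windows are retained, since with only two reads per gene-sized
  clone discarding the middle of a read would destroy coverage;
- a read shorter than the window is dropped (no window exists).

Dropped reads are carried through to the report, because an all-reads-
dropped clone Fails for sequencing reasons, not biological ones, and
the report should let the user tell the difference.

## Read placement

Each kept read is aligned locally (Smith–Waterman with affine gaps)
against the reference on both strands, and the higher-scoring strand
is kept (ties resolve to the forward strand).  The dynamic program is
Biopython's `PairwiseAligner`; default scores are +1 match, −2
mismatch, −4 gap open, −3 gap extend — the scheme Sanger-era
aligners conventionally use, configurable throughout.  A
placement is accepted only if its score reaches 30 and its identity
reaches 0.80; anything below is reported as unplaced rather than
forced onto the backbone.

For references longer than 20 kb the read is first localised by exact
15-mer seeding (densest-diagonal clustering), and the DP runs only in
the candidate window.  For contig-versus-reference alignments whose
DP matrix would exceed 10⁸ cells, the alignment is computed by
edlib's banded edit-distance algorithm in infix mode and rescored
under the configured scheme; for the near-identical sequences this
pipeline compares, the two routes give the same alignment.  Small
problems always take the full-DP route, which is the one checked
against an independent unbanded Gotoh oracle in the tests.

## Pileup and consensus

One placement per read (the best one) contributes observations to
pileup columns keyed by reference position; bases a read inserts
between reference positions p and p+1 occupy anchored insertion
columns (p, 1), (p, 2), …  Three kinds of observation exist:

- a base with its Phred score;
- a gap over a reference base (the read deletes it), weighted by the
  minimum of the flanking read qualities;
- a gap at an insertion column from reads that span the junction
  *without* inserting, weighted likewise — so an insertion must
  outweigh the non-inserting coverage to reach the consensus.

The consensus call per column sums the support for each candidate
symbol (A/C/G/T/gap).  The top symbol wins; symbols within
`tie_margin` (default 0, i.e. exact ties) of the top form the tied
set and yield the IUPAC code of the tied bases.  A gap tied with a
base resolves to the base, so the conflict surfaces downstream as a
discrepancy for review instead of being silently dropped.  The
consensus quality is the top support minus all other support, clamped
to [0, 90]; the reference itself never contributes an observation.
This reproduces the intended qualitative behaviour — a single clean
read yields consensus quality near its own scores, two agreeing reads
add up, conflicting evidence subtracts, and an exact tie is quality
0 — without claiming to be a calibrated error probability.

Maximal runs of contiguous covered reference positions become
contigs; coverage holes therefore split the consensus, and uncovered
reference regions are never backbone-filled.  Columns whose consensus
is a gap are elided from the contig sequence.

## Contig comparison and discrepancies

Each contig is re-aligned to the reference with the same scoring
scheme.  After the best local segment is taken, unaligned contig
stretches of at least 30 bases are realigned against the full
reference iteratively, which is what exposes rearrangements and
terminal-repeat artefacts as multiple segments.  The topology is
classified as complete (one segment spanning the whole reference),
partial, multiple (≥2 segments) or none, with the covered reference
fraction computed from the union of segment intervals.

Every non-identical alignment column yields a discrepancy; runs of
adjacent inserted or deleted bases merge into one multi-base event.
Indels are shifted to their leftmost equivalent position in repeat
context so the notation is deterministic.  Notation is the compact
positional style `254C>T` / `599_600insT` / `577delA` /
`577_579delACG`.  Reported qualities are the consensus quality at the
site (insertions: minimum over the inserted bases; deletions: minimum
flanking contig quality).  An IUPAC consensus base differing from the
reference counts as a substitution.

Note that a local aligner trims mismatches at the extreme ends of
very short sequences (extending past a terminal mismatch lowers the
score), so discrepancies within a few bases of a contig end may
instead appear as a slightly shortened alignment — the same behaviour
any local-alignment comparator exhibits.

## Verdict

Pass requires, simultaneously: a contig exists, zero discrepancies,
exactly one alignment segment, that segment covers the entire
reference, the contig is not longer than the reference, and mean
consensus quality is strictly greater than 20 (a mean of exactly 20
is a Review).  The only Fail is "no contig".  Review sub-reasons are
assigned by the first failing requirement in a fixed priority order
(no contig → discrepancies → multiple alignments → no alignment →
partial alignment → contig longer than reference → low quality), so
reports are deterministic.  "Alignment length equals the reference
length" is interpreted as the reference span of the single segment;
at the Pass boundary (zero discrepancies) this coincides with the
contig-length reading.  "No alignment" covers the corner where a
contig exists but nothing aligns; it remains a Review because the
assembler did find a contig.

Coverage gaps are reported as maximal 1-based reference intervals
that either lack any contig base (`uncovered`) or are covered only at
consensus quality below 20 (`low_quality`).  A reference position
whose column calls a consensus gap (a deletion) counts as uncovered
by this definition, which makes single-base "gaps" appear alongside
deletion discrepancies — intentional, as both mark unverified bases.

For circular references an advisory flag is raised when one to three
segments exist and one of them spans the entire reference — the
pattern reads crossing the origin of a circular molecule produce.
The flag never upgrades a verdict; true circular-coordinate
(rotation-search) alignment is out of scope, and plasmids should be
sequenced as if linear where possible.

## Synthetic data generator

The generator emulates single-pass Sanger sequencing of verified
constructs:

- **References** are i.i.d. random DNA with adjustable GC content; an
  optional terminal inexact repeat (a diverged copy of the sequence
  start placed at the end) recreates the repeat-induced
  multiple-alignment scenario.
- **Quality profile**: linear ramp from Q8 over the first 25 bases,
  plateau at peak Q50 through the usable span of 850 bases, then a
  linear decay of 1 Phred point per base, with Gaussian jitter
  (σ = 2); read length 950.  These figures represent a good modern
  single-pass Sanger run, where 800–1000 bases are usable at high
  quality; the profile shape and every parameter are configurable.
- **Errors** are independent per-base miscalls with probability
  10^(−Q/10) (uniform wrong base), i.e. the simulator is exactly
  Phred-calibrated, which the tests verify binomially at Q20.  Indel
  errors are off by default and available via `indel_rate`.
- **Sequencing modes**: a forward/reverse read pair for gene-sized
  clones, and an evenly spaced alternating-strand primer walk for
  plasmid-scale templates.  In both modes primers sit in 60 bp random
  vector flanks added around the construct, as real sequencing
  primers do, so that after quality clipping the construct itself
  remains covered end to end.
- All randomness flows through explicit integer seeds into numpy
  PCG64 generators; identical seeds give byte-identical projects.

What the simulator does **not** model: chromatogram-level artefacts
(dye blobs, peak compression), systematic error hotspots
(homopolymer slippage), vector contamination, chimeric reads, or
correlated errors between the two strands.  Passing tests therefore
demonstrate the correctness of the pipeline's logic under a
Phred-faithful error model, not robustness to every pathology of real
trace data.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline on 100
simulated gene-sized clones (900 bp, two reads, 0–3 planted
variants), 5–10 coverage-hole plasmids (3 kb), and one long-template
smoke test (100 kb reference, 900-read primer walk) — sizes chosen to
exercise every code path, including the seeded-placement and banded-
alignment routes, at laptop scale.  Planted variants in the recovery
tests keep 80 bases clear of the construct ends and 40 bases of each
other, and indels are chosen non-left-shiftable so the planted
notation is the canonical one.  Exact recovery is required in ≥99% of
replicates: with two Q50 reads a site is miscalled on both strands
(producing a spurious IUPAC substitution) only rarely, and one such
event per 100 clones is within expectation.

Tie-breaking is deterministic everywhere: equal strand scores go to
"+", co-optimal alignments take the aligner's first traceback, and
equal-support consensus ties produce IUPAC codes.  Coordinates are
0-based half-open internally and 1-based inclusive in all reports.

## Known limitations

- Consensus qualities are a support-minus-conflict heuristic, not
  calibrated error probabilities; they are meant for ranking and
  thresholding (the Q20 report threshold), not statistics.
- One placement per read: chimeric reads are not split, they simply
  align by their dominant segment or go unplaced.
- Circular molecules are handled only via the advisory flag.
- The iterative multi-segment contig aligner takes the full-DP route
  only below the cell limit; extremely large *and* rearranged contigs
  fall back to a single banded alignment.
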