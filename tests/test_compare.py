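import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqverify import (ReferenceSeq, ScoringScheme, align_contig,
                       call_discrepancies, circular_diagnosis, classify,
                       parse_notation)
from seqverify.compare import AlignmentSegment
from seqverify.refassembly import Contig
from seqverify.simdata import (Variant, mutate, random_variants,
                               simulate_reference)

from conftest import random_ref


def mk_contig(bases, quals=None, cid="c"):
    if quals is None:
        quals = [60] * len(bases)
    return Contig(cid, bases, np.asarray(quals), (0, len(bases)),
                  [(i, 0) for i in range(len(bases))])


def one_segment(contig, reference, **scheme):
    scoring = ScoringScheme(min_placement_score=5.0, min_identity=0.5,
                            **scheme)
    segments = align_contig(contig, reference, scoring, min_segment_len=4)
    assert len(segments) == 1
    return segments[0]


class TestAlignContig:
    def test_identical_contig_single_full_segment(self, scoring):
        ref = random_ref(700, seed=1)
        segs = align_contig(mk_contig(ref.bases), ref, scoring)
        assert len(segs) == 1
        s = segs[0]
        assert s.ref_interval == (0, 700)
        assert s.contig_interval == (0, 700)
        assert s.identity == 1.0

    def test_truncated_contig_partial_segment(self, scoring):
        ref = random_ref(950, seed=2)
        segs = align_contig(mk_contig(ref.bases[:652]), ref, scoring)
        assert len(segs) == 1
        assert segs[0].ref_interval == (0, 652)

    def test_rearranged_contig_two_segments(self, scoring):
        # contig carries two separate reference pieces -> two alignments
        ref = random_ref(700, seed=3)
        contig = mk_contig(ref.bases[0:400] + ref.bases[550:700])
        segs = align_contig(contig, ref, scoring)
        assert len(segs) == 2
        assert segs[0].ref_interval == (0, 400)
        assert segs[1].ref_interval == (550, 700)
        assert segs[0].contig_interval == (0, 400)
        assert segs[1].contig_interval == (400, 550)

    def test_inexact_terminal_repeat_splits_alignment(self, scoring):
        # reference ends with a diverged copy of its start; the contig's
        # tail matches the start exactly, so the tail aligns separately
        ref = simulate_reference(760, seed=13, terminal_repeat=(100, 40))
        contig = mk_contig(ref.bases[:660] + ref.bases[:100])
        segs = align_contig(contig, ref, scoring)
        assert len(segs) == 2
        assert classify(segs, ref).category == "multiple"

    def test_empty_contig_rejected(self, scoring):
        with pytest.raises(ValueError):
            align_contig(mk_contig(""), random_ref(50, seed=1), scoring)


FLANK_L = "ATTGCGTCAT"
FLANK_R = "GACCTGAAGT"


class TestCallDiscrepancies:
    def test_identical_sequences_no_discrepancies(self, scoring):
        ref = random_ref(300, seed=4)
        contig = mk_contig(ref.bases)
        seg = align_contig(contig, ref, scoring)[0]
        assert call_discrepancies(seg, contig, ref) == []

    def test_substitution_notation(self):
        # ACGT core with a G>A substitution, inside matching flanks
        ref = ReferenceSeq("r", FLANK_L + "ACGT" + FLANK_R)
        contig = mk_contig(FLANK_L + "ACAT" + FLANK_R)
        seg = one_segment(contig, ref)
        discrepancies = call_discrepancies(seg, contig, ref)
        assert [d.notation for d in discrepancies] == ["13G>A"]
        assert discrepancies[0].kind == "substitution"

    def test_insertion_left_aligned_notation(self):
        # inserted G next to an existing G shifts to the leftmost placement
        ref = ReferenceSeq("r", FLANK_L + "ACGT" + FLANK_R)
        contig = mk_contig(FLANK_L + "ACGGT" + FLANK_R)
        seg = one_segment(contig, ref)
        discrepancies = call_discrepancies(seg, contig, ref)
        assert [d.notation for d in discrepancies] == ["12_13insG"]

    def test_multibase_deletion_merged_into_one_event(self):
        # flanks long enough that bridging the 4-base gap beats splitting
        left, right = FLANK_L * 2, FLANK_R * 2
        ref = ReferenceSeq("r", left + "ACGTTGCA" + right)
        contig = mk_contig(left + "ACCA" + right)  # GTTG deleted
        seg = one_segment(contig, ref)
        discrepancies = call_discrepancies(seg, contig, ref)
        assert len(discrepancies) == 1
        d = discrepancies[0]
        assert d.kind == "deletion" and len(d.ref_allele) == 4

    def test_discrepancy_carries_contig_quality(self):
        ref = ReferenceSeq("r", FLANK_L + "ACGT" + FLANK_R)
        bases = FLANK_L + "ACAT" + FLANK_R
        quals = [60] * len(bases)
        quals[12] = 51  # the substituted base
        contig = mk_contig(bases, quals)
        seg = one_segment(contig, ref)
        [d] = call_discrepancies(seg, contig, ref)
        assert d.contig_qual == 51

    def test_iupac_consensus_base_counts_as_substitution(self):
        ref = ReferenceSeq("r", FLANK_L + "ACGT" + FLANK_R)
        contig = mk_contig(FLANK_L + "ACRT" + FLANK_R)
        seg = one_segment(contig, ref, mismatch=-1.0)
        discrepancies = call_discrepancies(seg, contig, ref)
        assert [d.notation for d in discrepancies] == ["13G>R"]

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 4))
    def test_planted_variants_recovered_exactly(self, seed, k):
        scoring = ScoringScheme()
        ref = simulate_reference(600, seed=seed % 1000)
        variants = random_variants(ref, k, seed=seed)
        contig = mk_contig(mutate(ref, variants))
        segs = align_contig(contig, ref, scoring)
        assert len(segs) == 1
        found = [d.notation for d in call_discrepancies(segs[0], contig, ref)]
        expected = []
        for v in variants:
            if v.kind == "substitution":
                expected.append(
                    f"{v.ref_pos}{ref.bases[v.ref_pos - 1]}>{v.alleles}")
            else:
                expected.append(v.notation)
        assert sorted(found) == sorted(expected)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_swapping_sequences_maps_insertions_to_deletions(self, seed):
        ref = simulate_reference(300, seed=seed % 997)
        [v] = random_variants(ref, 1, seed=seed)
        mutated = mutate(ref, [v])
        scoring = ScoringScheme()

        def events(ref_seq, contig_seq):
            r = ReferenceSeq("r", ref_seq)
            c = mk_contig(contig_seq)
            segs = align_contig(c, r, scoring)
            return call_discrepancies(segs[0], c, r)

        fwd = events(ref.bases, mutated)
        rev = events(mutated, ref.bases)
        kinds = {"insertion": "deletion", "deletion": "insertion",
                 "substitution": "substitution"}
        assert [kinds[d.kind] for d in fwd] == [d.kind for d in rev]


class TestNotation:
    @pytest.mark.parametrize("text,kind,pos,ref,alt", [
        ("254C>T", "substitution", 254, "C", "T"),
        ("599_600insT", "insertion", 599, "", "T"),
        ("577delA", "deletion", 577, "A", ""),
        ("577_579delACG", "deletion", 577, "ACG", ""),
    ])
    def test_parse(self, text, kind, pos, ref, alt):
        d = parse_notation(text)
        assert (d.kind, d.ref_pos, d.ref_allele, d.contig_allele) == \
            (kind, pos, ref, alt)

    def test_roundtrip(self):
        for text in ["254C>T", "599_600insT", "577delA", "577_579delACG",
                     "1_2insACGT"]:
            assert parse_notation(text).notation == text

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            parse_notation("not-a-variant")


def seg(ref_start, ref_end, contig_start=0, cid="c"):
    return AlignmentSegment(cid, ref_start, ref_end, contig_start,
                            contig_start + (ref_end - ref_start), 100.0,
                            1.0, [])


class TestClassify:
    def test_single_full_span_is_complete(self):
        ref = random_ref(500, seed=5)
        c = classify([seg(0, 500)], ref)
        assert c.category == "complete"
        assert c.covered_ref_fraction == 1.0

    def test_two_segments_multiple(self):
        ref = random_ref(500, seed=5)
        assert classify([seg(0, 200), seg(300, 500)], ref).category == "multiple"

    def test_partial_span_fraction(self):
        ref = random_ref(950, seed=5)
        c = classify([seg(0, 652)], ref)
        assert c.category == "partial"
        assert c.covered_ref_fraction == pytest.approx(652 / 950)

    def test_no_segments(self):
        c = classify([], random_ref(100, seed=5))
        assert c.category == "none" and c.segment_count == 0

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 80), st.integers(1, 20)),
                    min_size=0, max_size=5),
           st.randoms(use_true_random=False))
    def test_pure_function_of_interval_set(self, raw, rnd):
        ref = random_ref(100, seed=5)
        segments = [seg(a, min(100, a + w)) for a, w in raw]
        shuffled = list(segments)
        rnd.shuffle(shuffled)
        a, b = classify(segments, ref), classify(shuffled, ref)
        assert (a.category, a.covered_ref_fraction, a.segment_count) == \
            (b.category, b.covered_ref_fraction, b.segment_count)


class TestCircularDiagnosis:
    def setup_method(self):
        self.ref = ReferenceSeq("p", random_ref(500, seed=6).bases,
                                circular=True)

    def test_full_span_plus_short_overhang_ok(self):
        assert circular_diagnosis([seg(0, 500), seg(0, 60, 500)], self.ref)

    def test_single_full_span_ok(self):
        assert circular_diagnosis([seg(0, 500)], self.ref)

    def test_fragmented_without_full_span_not_ok(self):
        segs = [seg(0, 100), seg(100, 250), seg(250, 400), seg(400, 500)]
        assert not circular_diagnosis(segs, self.ref)

    def test_linear_reference_never_flagged(self):
        linear = random_ref(500, seed=6)
        assert not circular_diagnosis([seg(0, 500)], linear)
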