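"""Isoform alignment, TM-domain mapping and truncation screening."""

import pytest

from sixtm.screen import (
    AlignmentResult,
    align_isoform,
    classify_truncation,
    extract_replaced_segments,
    is_selected,
    run_screen,
    tm_presence,
)
from sixtm.simulate import gen_isoform_benchmark

CANONICAL = (
    "MSTNG" * 4  # N-tail (20)
    + "LIVFLIVFLIVFLIVFLIVFL"  # a recognisable helix (21)
    + "STNGSTNGSTNGSTNGSTNG" * 10  # long hydrophilic tail
)


def brute_force_alignments(a, b, match=1, mismatch=-1, gap=-2):
    """Enumerate every global alignment of two short sequences."""
    best = [float("-inf"), []]

    def rec(i, j, ga, gb, score):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0], best[1] = score, [(ga, gb)]
            elif score == best[0]:
                best[1].append((ga, gb))
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, ga + a[i], gb + b[j], score + s)
        if i < len(a):
            rec(i + 1, j, ga + a[i], gb + "-", score + gap)
        if j < len(b):
            rec(i, j + 1, ga + "-", gb + b[j], score + gap)

    rec(0, 0, "", "", 0)
    return best[0], best[1]


class TestAlignIsoform:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_isoform(CANONICAL, CANONICAL)
        assert "-" not in aln.aligned_canonical
        assert "-" not in aln.aligned_isoform

    def test_n_terminal_deletion_opens_leading_gaps(self):
        iso = CANONICAL[50:]
        aln = align_isoform(CANONICAL, iso)
        assert aln.aligned_isoform.startswith("-" * 50)
        # degapping reproduces the inputs exactly
        assert aln.canonical == CANONICAL
        assert aln.isoform == iso

    def test_unit_score_alignment_matches_exhaustive_enumeration(self):
        # tiny case checkable by complete enumeration of all alignments
        best_score, best_alns = brute_force_alignments("MKT", "MT")
        assert best_score == 0
        assert ("MKT", "M-T") in best_alns
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 1, -1
        aligner.open_gap_score = aligner.extend_gap_score = -2
        assert aligner.score("MKT", "MT") == best_score

    def test_non_amino_acid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align_isoform("MKT", "M1T")
        with pytest.raises(ValueError, match="empty"):
            align_isoform("MKT", "")


class TestTmPresence:
    TM = ((3, 6), (9, 12), (15, 18), (21, 24), (27, 30), (33, 36), (39, 42))

    def _identity(self, n=50):
        seq = "A" * n
        return AlignmentResult(seq, seq, 0.0)

    def test_identity_alignment_keeps_all_domains(self):
        assert tm_presence(self._identity(), self.TM) == (True,) * 7

    def test_domain_opposite_gaps_is_absent(self):
        canonical = "A" * 50
        isoform = "--" + "-" * 4 + "A" * 44  # TM1 (residues 3-6) fully gapped
        aln = AlignmentResult(canonical, isoform, 0.0)
        presence = tm_presence(aln, self.TM)
        assert presence[0] is False
        assert all(presence[1:])

    def test_fractional_coverage_threshold(self):
        canonical = "A" * 23 + "A" * 27
        # 12 of the first 23 residues aligned (52%): present at the 0.5 cutoff
        isoform = "-" * 11 + "A" * 39
        aln = AlignmentResult(canonical, isoform, 0.0)
        tm = ((1, 23), (30, 40), (41, 43), (44, 45), (46, 47), (48, 49), (50, 50))
        assert tm_presence(aln, tm)[0] is True
        assert tm_presence(aln, tm, coverage_min=0.6)[0] is False

    def test_lowering_coverage_min_never_removes_a_domain(self):
        canonical = "A" * 50
        isoform = "-" * 13 + "A" * 37
        aln = AlignmentResult(canonical, isoform, 0.0)
        grid = [0.9, 0.7, 0.5, 0.3, 0.1]
        vectors = [tm_presence(aln, self.TM, c) for c in grid]
        for strict, loose in zip(vectors, vectors[1:]):
            assert all(l or not s for s, l in zip(strict, loose))


class TestClassifyTruncation:
    def test_all_present_is_full_receptor(self):
        call = classify_truncation("i", (True,) * 7)
        assert call.category == "full_7TM"
        assert call.n_tm == 7
        assert not is_selected(call)

    def test_missing_tm1_is_n_truncated_6tm(self):
        call = classify_truncation("i", (False,) + (True,) * 6)
        assert call.category == "N_trunc_6TM"
        assert call.n_tm == 6
        assert is_selected(call)

    def test_missing_tm7_is_c_truncated_6tm(self):
        call = classify_truncation("i", (True,) * 6 + (False,))
        assert call.category == "C_trunc_6TM"
        assert is_selected(call)

    def test_hydrophobic_replacement_rescues_missing_helix(self):
        call = classify_truncation("i", (False,) + (True,) * 6, {1: "L" * 21})
        assert call.category == "full_7TM"
        assert call.de_novo_helix_rescue
        assert call.n_tm == 7
        assert not is_selected(call)

    def test_hydrophilic_replacement_does_not_rescue(self):
        call = classify_truncation("i", (False,) + (True,) * 6, {1: "S" * 21})
        assert call.category == "N_trunc_6TM"
        assert not call.de_novo_helix_rescue

    def test_double_n_terminal_loss_is_5tm(self):
        call = classify_truncation("i", (False, False) + (True,) * 5)
        assert call.category == "N_trunc_5TM"
        assert is_selected(call)


class TestReplacedSegments:
    def test_insertion_next_to_missing_domain_is_extracted(self):
        canonical = "----" + "A" * 10
        isoform = "LLLL" + "----" + "A" * 6
        aln = AlignmentResult(canonical, isoform, 0.0)
        tm = ((1, 4), (5, 5), (6, 6), (7, 7), (8, 8), (9, 9), (10, 10))
        presence = tm_presence(aln, tm)
        assert presence[0] is False
        segments = extract_replaced_segments(aln, tm, presence)
        assert segments[1] == "LLLL"

    def test_plain_deletion_has_no_replacement(self):
        canonical = "A" * 12
        isoform = "----" + "A" * 8
        aln = AlignmentResult(canonical, isoform, 0.0)
        tm = ((1, 4), (5, 5), (6, 6), (7, 8), (9, 9), (10, 10), (11, 12))
        presence = tm_presence(aln, tm)
        assert extract_replaced_segments(aln, tm, presence) == {}


class TestRunScreen:
    def test_empty_record_list_selects_nothing(self):
        selected, all_calls, summary = run_screen([])
        assert selected == [] and all_calls == []
        assert summary.empty

    def test_planted_benchmark_recovered_exactly(self):
        mix = {"full": 5, "N_trunc_6TM": 3, "C_trunc_6TM": 2}
        records, truth = gen_isoform_benchmark(seed=42, category_mix=mix)
        selected, all_calls, _ = run_screen(records)
        got = {c.isoform_id: c.category for _, c in all_calls}
        for iso_id, info in truth["isoforms"].items():
            assert got[iso_id] == info["category"]
        assert {c.isoform_id for _, c in selected} == {
            i for i, info in truth["isoforms"].items() if info["selected"]
        }

    def test_fragments_never_reach_selection(self):
        records, _ = gen_isoform_benchmark(
            seed=3, category_mix={"fragment": 4, "N_trunc_6TM": 2}
        )
        selected, all_calls, _ = run_screen(records)
        frag_ids = {
            i.id for rs in records for i in rs.isoforms if i.fragment
        }
        assert frag_ids
        assert not frag_ids & {c.isoform_id for _, c in selected}
        assert all(
            c.category == "excluded_fragment"
            for _, c in all_calls
            if c.isoform_id in frag_ids
        )

    def test_summary_counts_match_calls(self):
        records, _ = gen_isoform_benchmark(
            seed=5, category_mix={"full": 2, "C_trunc_5TM": 2}
        )
        _, all_calls, summary = run_screen(records)
        assert summary["count"].sum() == len(all_calls)
        assert set(summary["category"]) == {c.category for _, c in all_calls}
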