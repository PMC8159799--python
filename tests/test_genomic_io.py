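"""I/O formats, coordinate conventions and spliced-sequence assembly."""

import pytest
from hypothesis import given, settings, strategies as st

from sixtm.genomic_io import (
    ExonInterval,
    FormatError,
    GenomeSequence,
    IsoformRecord,
    IsoformRecordSet,
    TranscriptModel,
    load_gene_models,
    load_isoform_records,
    load_score_track,
    read_genome,
    spliced_sequence,
    write_genome,
    write_gtf,
    write_isoform_records,
)

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def _write(path, text):
    path.write_text(text)
    return str(path)


@pytest.fixture
def genome_file(tmp_path):
    return _write(tmp_path / "g.fa", ">chr1\nAAGGTTCC\n")


class TestGeneModels:
    def test_bed_half_open_converted_to_one_based_closed(self, tmp_path, genome_file):
        bed = _write(tmp_path / "a.bed", "chr1\t2\t5\ttx1\t0\t+\n")
        transcripts, _ = load_gene_models(bed, genome_file)
        (tx,) = transcripts
        assert (tx.exons[0].start, tx.exons[0].end) == (3, 5)

    def test_gtf_coordinates_pass_through(self, tmp_path, genome_file):
        gtf = _write(
            tmp_path / "a.gtf",
            'chr1\tsrc\texon\t3\t5\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
        )
        transcripts, _ = load_gene_models(gtf, genome_file)
        assert (transcripts[0].exons[0].start, transcripts[0].exons[0].end) == (3, 5)

    def test_minus_strand_exons_ordered_five_prime_first(self, tmp_path, genome_file):
        gtf = _write(
            tmp_path / "a.gtf",
            'chr1\ts\texon\t1\t3\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\ts\texon\t6\t8\t.\t-\t.\tgene_id "g"; transcript_id "t";\n',
        )
        transcripts, _ = load_gene_models(gtf, genome_file)
        starts = [e.start for e in transcripts[0].exons]
        assert starts == [6, 1]  # 5'->3' on the minus strand is descending

    def test_unknown_chromosome_is_named_in_error(self, tmp_path, genome_file):
        gtf = _write(
            tmp_path / "a.gtf",
            'chrX\ts\texon\t1\t3\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
        )
        with pytest.raises(FormatError, match="chrX"):
            load_gene_models(gtf, genome_file)

    def test_malformed_line_reports_line_number(self, tmp_path, genome_file):
        gtf = _write(tmp_path / "a.gtf", "chr1\tonly\tthree\n")
        with pytest.raises(FormatError, match="line 1"):
            load_gene_models(gtf, genome_file)

    def test_gtf_round_trip_preserves_models(self, tmp_path, genome_file):
        exons = (
            ExonInterval("chr1", 6, 8, "-", "e2"),
            ExonInterval("chr1", 1, 3, "-", "e1"),
        )
        tx = TranscriptModel("t1", exons, "-", "g1")
        out = tmp_path / "rt.gtf"
        write_gtf([tx], out)
        loaded, _ = load_gene_models(str(out), genome_file)
        assert loaded[0].exons == exons
        assert loaded[0].strand == "-"
        assert loaded[0].gene == "g1"

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TranscriptModel(
                "t",
                (ExonInterval("c", 1, 5), ExonInterval("c", 4, 8)),
                "+",
            )


class TestSplicedSequence:
    GENOME = {"chr1": GenomeSequence("chr1", "AAGGTTCC")}

    def test_single_exon_plus(self):
        tx = TranscriptModel("t", (ExonInterval("chr1", 1, 3),), "+")
        assert spliced_sequence(tx, self.GENOME) == "AAG"

    def test_two_exon_minus_is_revcomp_of_concatenation(self):
        exons = (
            ExonInterval("chr1", 6, 8, "-"),
            ExonInterval("chr1", 1, 3, "-"),
        )
        tx = TranscriptModel("t", exons, "-")
        assert spliced_sequence(tx, self.GENOME) == "GGACTT"

    def test_full_length_identity(self):
        tx = TranscriptModel("t", (ExonInterval("chr1", 1, 8),), "+")
        assert spliced_sequence(tx, self.GENOME) == "AAGGTTCC"

    def test_out_of_bounds_exon_errors(self):
        tx = TranscriptModel("t", (ExonInterval("chr1", 5, 20),), "+")
        with pytest.raises(ValueError, match="out of bounds"):
            spliced_sequence(tx, self.GENOME)

    @given(data=st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_length_and_strand_symmetry_properties(self, data):
        residues = data.draw(st.text(alphabet="ACGTN", min_size=10, max_size=60))
        genome = {"c": GenomeSequence("c", residues)}
        n = len(residues)
        bounds = sorted(
            data.draw(
                st.lists(st.integers(1, n), min_size=2, max_size=6, unique=True)
            )
        )
        exons_plus = []
        for s, e in zip(bounds[::2], bounds[1::2]):
            exons_plus.append(ExonInterval("c", s, e, "+"))
        tx_plus = TranscriptModel("p", tuple(exons_plus), "+")
        seq_plus = spliced_sequence(tx_plus, genome)
        assert len(seq_plus) == sum(len(e) for e in exons_plus)

        exons_minus = tuple(
            ExonInterval("c", e.start, e.end, "-") for e in reversed(exons_plus)
        )
        tx_minus = TranscriptModel("m", exons_minus, "-")
        seq_minus = spliced_sequence(tx_minus, genome)
        assert seq_minus == seq_plus.translate(REVCOMP)[::-1]


class TestScoreTrack:
    def test_bedgraph_interval_expanded_per_base(self, tmp_path):
        path = _write(tmp_path / "s.bedgraph", "chr1\t0\t4\t0.5\n")
        track = load_score_track(path)["chr1"]
        assert [track.get(p) for p in range(1, 5)] == [0.5] * 4
        assert track.get(5) is None

    def test_half_open_boundary_between_rows(self, tmp_path):
        path = _write(tmp_path / "s.bedgraph", "chr1\t0\t2\t0.0\nchr1\t2\t4\t1.0\n")
        track = load_score_track(path)["chr1"]
        assert [track.get(p) for p in (1, 2, 3, 4)] == [0.0, 0.0, 1.0, 1.0]

    def test_score_above_one_rejected(self, tmp_path):
        path = _write(tmp_path / "s.bedgraph", "chr1\t0\t4\t1.2\n")
        with pytest.raises(FormatError, match="range from 0 to 1"):
            load_score_track(path)

    def test_negative_score_rejected(self, tmp_path):
        path = _write(tmp_path / "s.bedgraph", "chr1\t0\t1\t-0.1\n")
        with pytest.raises(FormatError):
            load_score_track(path)

    def test_fixed_step_wiggle(self, tmp_path):
        path = _write(
            tmp_path / "s.wig", "fixedStep chrom=chr2 start=11 step=2\n0.1\n0.2\n"
        )
        track = load_score_track(path)["chr2"]
        assert track.get(11) == 0.1
        assert track.get(13) == 0.2
        assert track.get(12) is None


class TestIsoformRecords:
    def _record(self, n_tm=7, fragment=False):
        seq = "M" + "A" * 200
        tm = tuple((10 + 25 * i, 30 + 25 * i) for i in range(n_tm))
        return {
            "gene": "OPRX1",
            "canonical": {
                "sequence": seq,
                "tm_starts": [s for s, _ in tm],
                "tm_ends": [e for _, e in tm],
            },
            "isoforms": [{"id": "iso1", "sequence": seq[50:], "fragment": fragment}],
        }

    def test_seven_tm_record_accepted(self, tmp_path):
        import json

        path = _write(tmp_path / "r.json", json.dumps([self._record()]))
        (rs,) = load_isoform_records(path)
        assert len(rs.tm_domains) == 7

    def test_six_tm_canonical_rejected(self, tmp_path):
        import json

        path = _write(tmp_path / "r.json", json.dumps([self._record(n_tm=6)]))
        with pytest.raises(ValueError, match="exactly 7 TM"):
            load_isoform_records(path)

    def test_fragment_flag_preserved(self, tmp_path):
        import json

        path = _write(tmp_path / "r.json", json.dumps([self._record(fragment=True)]))
        (rs,) = load_isoform_records(path)
        assert rs.isoforms[0].fragment is True

    def test_json_round_trip(self, tmp_path):
        rs = IsoformRecordSet(
            "G1",
            "M" + "A" * 200,
            tuple((10 + 25 * i, 30 + 25 * i) for i in range(7)),
            (IsoformRecord("i1", "A" * 50, True),),
        )
        out = tmp_path / "rt.json"
        write_isoform_records([rs], out)
        (loaded,) = load_isoform_records(out)
        assert loaded == rs


class TestGenomeFasta:
    def test_round_trip_and_uppercasing(self, tmp_path):
        store = {"c1": GenomeSequence("c1", "acgtn")}
        out = tmp_path / "g.fa"
        write_genome(store, out)
        loaded = read_genome(out)
        assert loaded["c1"].residues == "ACGTN"

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            GenomeSequence("c", "ACGU")
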