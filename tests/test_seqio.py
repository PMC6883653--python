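"""Sequence I/O, preprocessing, PAF labeling and oriented output."""

import pytest

from readorient import seqio
from readorient.seqio import (
    MappedLabelFilter,
    Orientation,
    ParseError,
    SeqRecord,
    SourceKind,
)


def paf_line(read_id, strand, mapq, target="tx1"):
    # 12 mandatory PAF columns
    return "\t".join(
        [read_id, "1000", "0", "900", strand, target, "1500", "10", "910", "850",
         "900", str(mapq)]
    )


@pytest.fixture
def paf_file(tmp_path):
    def _write(lines, name="aln.paf"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


class TestReadSequences:
    def test_fasta_uppercases_and_converts_u(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">r1\nacgu\n")
        (rec,) = seqio.read_sequences(path)
        assert rec.read_id == "r1"
        assert rec.seq == "ACGT"
        assert rec.qual is None

    def test_fastq_keeps_quality(self, fastq_file):
        path = fastq_file([("r1", "ACGT", "IIII")])
        (rec,) = seqio.read_sequences(path)
        assert rec.seq == "ACGT" and rec.qual == "IIII"

    def test_fastq_length_mismatch_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nII\n")
        with pytest.raises(ParseError, match="malformed"):
            seqio.read_sequences(path)

    def test_auto_detection_and_order(self, fasta_file):
        path = fasta_file([("a", "ACGT"), ("b", "GGGG"), ("c", "TTTT")])
        recs = seqio.read_sequences(path, format="auto")
        assert [r.read_id for r in recs] == ["a", "b", "c"]

    def test_unknown_first_byte(self, tmp_path):
        path = tmp_path / "junk.txt"
        path.write_text("#not a sequence file\n")
        with pytest.raises(ParseError, match="auto-detect"):
            seqio.read_sequences(path)


class TestPreprocess:
    def test_discards_reads_with_n(self):
        recs = [SeqRecord("a", "ACGTN"), SeqRecord("b", "ACGT")]
        kept, log = seqio.preprocess(recs, trim_n=0, min_len=1)
        assert [r.read_id for r in kept] == ["b"]
        assert log.n_contains_n == 1 and log.n_kept == 1

    def test_symmetric_trim(self):
        kept, _ = seqio.preprocess([SeqRecord("a", "ACGTACGT")], trim_n=2, min_len=1)
        assert kept[0].seq == "GTAC"

    def test_trim_to_nothing_is_discarded(self):
        kept, log = seqio.preprocess([SeqRecord("a", "ACGT")], trim_n=2, min_len=1)
        assert kept == [] and log.n_too_short == 1

    def test_quality_trimmed_with_sequence(self):
        recs = [SeqRecord("a", "ACGTAC", qual="012345")]
        kept, _ = seqio.preprocess(recs, trim_n=1, min_len=1)
        assert kept[0].seq == "CGTA" and kept[0].qual == "1234"

    def test_never_lengthens_and_counts_are_exact(self, random_seq):
        recs = [SeqRecord(f"r{i}", random_seq(60, "ACGTN")) for i in range(30)]
        kept, log = seqio.preprocess(recs, trim_n=3, min_len=50)
        assert all(len(k.seq) <= 60 for k in kept)
        assert log.n_input == 30
        assert log.n_kept + log.n_contains_n + log.n_too_short == 30


class TestPafLabels:
    def test_forward_label_at_max_mapq(self, paf_file):
        labels, excluded = seqio.parse_paf_labels(paf_file([paf_line("r1", "+", 60)]))
        assert labels == {"r1": Orientation.FORWARD}
        assert not excluded

    def test_low_mapq_excluded(self, paf_file):
        labels, excluded = seqio.parse_paf_labels(paf_file([paf_line("r2", "-", 30)]))
        assert labels == {}
        assert excluded["low_mapq"] == 1

    def test_multimapping_excluded(self, paf_file):
        path = paf_file([paf_line("r3", "+", 60), paf_line("r3", "-", 60, "tx2")])
        labels, excluded = seqio.parse_paf_labels(path)
        assert labels == {}
        assert excluded["multimapping"] == 1

    def test_reverse_strand(self, paf_file):
        labels, _ = seqio.parse_paf_labels(paf_file([paf_line("r4", "-", 60)]))
        assert labels == {"r4": Orientation.REVERSE}

    def test_kept_plus_excluded_covers_all_reads(self, paf_file):
        lines = [
            paf_line("a", "+", 60),
            paf_line("b", "-", 10),
            paf_line("c", "+", 60),
            paf_line("c", "+", 60, "tx2"),
        ]
        labels, excluded = seqio.parse_paf_labels(paf_file(lines))
        assert len(labels) + sum(excluded.values()) == 3

    def test_unknown_strand_symbol(self, paf_file):
        bad = paf_line("r1", "+", 60).split("\t")
        bad[4] = "?"
        with pytest.raises(ParseError, match="strand"):
            seqio.parse_paf_labels(paf_file(["\t".join(bad)]))

    def test_short_line_reports_line_number(self, paf_file):
        with pytest.raises(ParseError, match=":1:"):
            seqio.parse_paf_labels(paf_file(["r1\t+\t60"]))

    def test_configurable_mapq_threshold(self, paf_file):
        path = paf_file([paf_line("r1", "+", 30)])
        labels, _ = seqio.parse_paf_labels(path, MappedLabelFilter(min_mapq=30))
        assert "r1" in labels

    def test_mapq_range_validated(self):
        with pytest.raises(ValueError):
            MappedLabelFilter(min_mapq=99)


class TestBuildLabeledDataset:
    def test_annotation_all_forward(self, fasta_file):
        path = fasta_file([("t1", "ACGT"), ("t2", "GGGG"), ("t3", "TTTT")])
        recs = seqio.build_labeled_dataset(SourceKind.ANNOTATION, path)
        assert len(recs) == 3
        assert all(r.label is Orientation.FORWARD for r in recs)

    def test_mapped_joins_with_paf(self, fasta_file, tmp_path):
        path = fasta_file([(f"r{i}", "ACGTACGT") for i in range(4)])
        paf = tmp_path / "m.paf"
        paf.write_text(paf_line("r0", "+", 60) + "\n" + paf_line("r2", "-", 60) + "\n")
        recs = seqio.build_labeled_dataset(SourceKind.MAPPED, path, paf_path=paf)
        assert {r.read_id: r.label for r in recs} == {
            "r0": Orientation.FORWARD,
            "r2": Orientation.REVERSE,
        }

    def test_experimental_converts_u_and_labels_forward(self, tmp_path):
        path = tmp_path / "drs.fasta"
        path.write_text(">d1\nacgu\n")
        (rec,) = seqio.build_labeled_dataset(SourceKind.EXPERIMENTAL, path)
        assert rec.seq == "ACGT" and rec.label is Orientation.FORWARD

    def test_mapped_without_paf_is_config_error(self, fasta_file):
        path = fasta_file([("r1", "ACGT")])
        with pytest.raises(ValueError, match="PAF"):
            seqio.build_labeled_dataset(SourceKind.MAPPED, path)


class TestWriteOriented:
    def test_flip_rule_and_revcomp(self, tmp_path):
        recs = [SeqRecord("hi", "AACG"), SeqRecord("lo", "AACG")]
        out = tmp_path / "out.fasta"
        n = seqio.write_oriented(recs, [0.9, 0.1], out, format="fasta")
        assert n == 1
        text = out.read_text()
        assert "CGTT" in text  # flipped
        assert "AACG" in text  # kept
        assert "ro_flipped=1" in text and "ro_flipped=0" in text

    def test_score_at_threshold_not_flipped(self, tmp_path):
        out = tmp_path / "o.fasta"
        n = seqio.write_oriented([SeqRecord("r", "AACG")], [0.5], out)
        assert n == 0
        assert "AACG" in out.read_text()

    def test_fastq_flip_reverses_quality(self, tmp_path):
        recs = [SeqRecord("r", "AACG", qual="0123")]
        out = tmp_path / "o.fastq"
        seqio.write_oriented(recs, [0.99], out, format="fastq")
        lines = out.read_text().splitlines()
        assert lines[1] == "CGTT" and lines[3] == "3210"

    def test_round_trip_all_forward(self, tmp_path, random_seq):
        recs = [SeqRecord(f"r{i}", random_seq(80)) for i in range(5)]
        out = tmp_path / "rt.fasta"
        seqio.write_oriented(recs, [0.0] * 5, out)
        back = seqio.read_sequences(out)
        assert [r.seq for r in back] == [r.seq for r in recs]

    def test_score_count_mismatch(self, tmp_path):
        with pytest.raises(ValueError, match="one score per record"):
            seqio.write_oriented([SeqRecord("r", "ACGT")], [], tmp_path / "x.fasta")
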