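"""The synthetic transcriptome / read simulator."""

import numpy as np
import pytest
from scipy import stats

from readorient import synthetic
from readorient.features import kmer_frequency_vector, KmerSpec, reverse_complement
from readorient.seqio import Orientation
from readorient.synthetic import SyntheticConfig, generate_transcripts, make_read_set


class TestConfigValidation:
    def test_min_length_floor(self):
        with pytest.raises(ValueError, match="length_range"):
            SyntheticConfig(length_range=(100, 500))

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="composition"):
            SyntheticConfig(base_composition=(0.5, 0.5, 0.5, 0.5))

    def test_motif_length_bounds(self):
        with pytest.raises(ValueError, match="4-8"):
            SyntheticConfig(motifs=("ACG",))


class TestGenerateTranscripts:
    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(n_seqs=20, length_range=(250, 400), seed=4)
        a = generate_transcripts(cfg)
        b = generate_transcripts(cfg)
        assert [r.seq for r in a] == [r.seq for r in b]
        assert [r.motif_positions for r in a] == [r.motif_positions for r in b]

    def test_all_forward_labels(self):
        cfg = SyntheticConfig(n_seqs=5, length_range=(250, 300), seed=0)
        assert all(r.label is Orientation.FORWARD for r in generate_transcripts(cfg))

    def test_planted_count_tracks_poisson_mean(self):
        cfg = SyntheticConfig(
            n_seqs=200, length_range=(1000, 1000), motif_density=0.01, seed=2
        )
        counts = [len(r.motif_positions) for r in generate_transcripts(cfg)]
        assert abs(np.mean(counts) - 10) < 2

    def test_motifs_actually_planted_at_positions(self):
        cfg = SyntheticConfig(n_seqs=10, length_range=(500, 600), seed=3)
        for rec in generate_transcripts(cfg):
            for pos in rec.motif_positions:
                assert any(
                    rec.seq[pos : pos + len(m)] == m for m in cfg.motifs
                ), (rec.read_id, pos)

    def test_polya_tail_appended(self):
        cfg = SyntheticConfig(
            n_seqs=30, length_range=(250, 250), polya_mean=30, motif_density=0, seed=1
        )
        tails = [len(r.seq) - 250 for r in generate_transcripts(cfg)]
        assert min(tails) >= 1
        assert 15 < np.mean(tails) < 45
        assert all(r.seq.endswith("A") for r in generate_transcripts(cfg))

    def test_null_config_has_no_strand_asymmetry(self):
        """k-mer spectra of the forward and reverse strands are
        indistinguishable when no motifs are planted (chi-square)."""
        cfg = SyntheticConfig(
            n_seqs=60, length_range=(500, 500), motif_density=0.0, seed=8
        )
        spec = KmerSpec(3)
        fwd = np.zeros(spec.n_features)
        rev = np.zeros(spec.n_features)
        for rec in generate_transcripts(cfg):
            fwd += kmer_frequency_vector(rec.seq, spec)
            rev += kmer_frequency_vector(reverse_complement(rec.seq), spec)
        block = spec.block_slice(3)
        # counts scaled back to pseudo-observations for the test
        f = fwd[block] / fwd[block].sum() * 5000
        r = rev[block] / rev[block].sum() * 5000
        p = stats.chisquare(f, (f + r) / 2).pvalue
        assert p > 0.01


class TestMakeReadSet:
    def test_noise_free_reads_equal_transcripts_or_revcomp(self):
        cfg = SyntheticConfig(n_seqs=30, length_range=(250, 400), seed=6)
        tr = generate_transcripts(cfg)
        reads = make_read_set(tr, cfg)
        by_id = {t.read_id: t.seq for t in tr}
        for read in reads:
            source = by_id[read.read_id.rsplit("_r", 1)[0]]
            if read.label is Orientation.FORWARD:
                assert read.seq == source
            else:
                assert read.seq == reverse_complement(source)

    def test_error_rate_matches_recorded_events(self):
        cfg = SyntheticConfig(
            n_seqs=50,
            length_range=(500, 800),
            sub_rate=0.05,
            ins_rate=0.025,
            del_rate=0.025,
            seed=12,
        )
        tr = generate_transcripts(cfg)
        reads = make_read_set(tr, cfg)
        per_base = np.array(
            [r.n_error_events / r.source_length for r in reads]
        )
        assert abs(per_base.mean() - 0.10) < 0.02

    def test_label_balance_is_binomial(self):
        cfg = SyntheticConfig(n_seqs=1000, length_range=(250, 260), seed=13)
        reads = make_read_set(generate_transcripts(cfg), cfg)
        frac_rev = np.mean([r.label is Orientation.REVERSE for r in reads])
        assert abs(frac_rev - 0.5) < 0.05

    def test_truncation_shortens_from_5prime(self):
        cfg = SyntheticConfig(
            n_seqs=40,
            length_range=(600, 600),
            truncation_5p_prob=1.0,
            truncation_mean=100,
            motif_density=0,
            seed=14,
        )
        tr = generate_transcripts(cfg)
        reads = make_read_set(tr, cfg)
        by_id = {t.read_id: t.seq for t in tr}
        shorter = 0
        for read in reads:
            seq = read.seq
            if read.label is Orientation.REVERSE:
                seq = reverse_complement(seq)
            source = by_id[read.read_id.rsplit("_r", 1)[0]]
            assert source.endswith(seq)  # 3' end intact
            shorter += len(seq) < 600
        assert shorter > 30

    def test_reads_per_transcript_in_range(self):
        cfg = SyntheticConfig(
            n_seqs=20, length_range=(250, 300), reads_per_transcript=(2, 5), seed=15
        )
        reads = make_read_set(generate_transcripts(cfg), cfg)
        from collections import Counter

        sizes = Counter(r.read_id.rsplit("_r", 1)[0] for r in reads).values()
        assert all(2 <= s <= 5 for s in sizes)

    def test_strand_clusters_are_orientation_homogeneous(self):
        cfg = SyntheticConfig(
            n_seqs=30, length_range=(250, 300), reads_per_transcript=(3, 8), seed=17
        )
        reads = make_read_set(generate_transcripts(cfg), cfg)
        by_cluster = {}
        for r in reads:
            by_cluster.setdefault(r.cluster_id, set()).add(r.label)
        assert all(len(v) == 1 for v in by_cluster.values())

    def test_cluster_by_strand_disabled_pools_both_strands(self):
        cfg = SyntheticConfig(
            n_seqs=40,
            length_range=(250, 300),
            reads_per_transcript=(6, 6),
            cluster_by_strand=False,
            seed=18,
        )
        reads = make_read_set(generate_transcripts(cfg), cfg)
        labels = {}
        for r in reads:
            labels.setdefault(r.cluster_id, set()).add(r.label)
        assert any(len(v) == 2 for v in labels.values())


class TestTruthTable:
    def test_round_trip(self, tmp_path):
        cfg = SyntheticConfig(n_seqs=10, length_range=(250, 300), seed=16)
        reads = make_read_set(generate_transcripts(cfg), cfg)
        path = tmp_path / "truth.tsv"
        synthetic.write_truth(reads, path)
        labels, clusters = synthetic.read_truth(path)
        assert len(labels) == len(reads)
        for r in reads:
            assert labels[r.read_id] == r.label.value
            assert clusters[r.read_id] == r.cluster_id
        assert set(labels.values()) <= {"FORWARD", "REVERSE"}
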