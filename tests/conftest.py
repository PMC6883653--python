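import numpy as np
import pytest

from readorient import models, synthetic
from readorient.seqio import Orientation, SeqRecord


@pytest.fixture
def fasta_file(tmp_path):
    def _write(entries, name="reads.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def fastq_file(tmp_path):
    def _write(entries, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq, qual in entries:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        return path

    return _write


@pytest.fixture
def random_seq():
    rng = np.random.default_rng(42)

    def _make(length, alphabet="ACGT"):
        return "".join(rng.choice(list(alphabet), size=length))

    return _make


def tiny_cnn_config(**overrides):
    """A small CNN for unit tests: 60-nt windows, narrow filters."""
    defaults = dict(
        conv_filters=(8, 8, 8),
        conv_widths=(7, 3, 2),
        pool_sizes=(2, 2, 2),
        dense_sizes=(16, 8),
        window=60,
        stride=30,
        epochs=3,
        batch_size=32,
        seed=0,
    )
    defaults.update(overrides)
    return models.CnnConfig(**defaults)


@pytest.fixture(name="tiny_cnn_config")
def tiny_cnn_config_fixture():
    return tiny_cnn_config


@pytest.fixture(scope="session")
def tiny_mlp_model():
    """A quickly trained MLP on strongly-motif-laden synthetic data."""
    cfg = synthetic.SyntheticConfig(
        n_seqs=200, length_range=(300, 500), motif_density=0.03, seed=5
    )
    transcripts = synthetic.generate_transcripts(cfg)
    seqs, labels = models.make_balanced_training_set(transcripts, seed=5)
    return models.train_mlp(
        seqs, labels, models.MlpConfig(k_max=3, epochs=15, seed=5)
    )


def forward_records(seqs):
    return [
        SeqRecord(f"r{i}", s, label=Orientation.FORWARD) for i, s in enumerate(seqs)
    ]
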