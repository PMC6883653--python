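"""Desk-scale benchmark conditions used by the test suite and the
reproduction script.

The reference conditions: 3,000 training and 1,000 held-out synthetic
transcripts, lengths 500-2,000 nt, ten planted hexamers at one motif per
100 nt, no poly-A tail.  Test reads are the held-out transcripts, each
reverse-complemented with probability 0.5; variants add a 10% per-base
error channel, symmetric 100-nt trimming, or remove the motif signal
entirely (the no-signal null, where any accuracy away from 0.5 indicates
leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import cluster_vote, inference, models
from .seqio import Orientation, preprocess
from .synthetic import (
    SyntheticConfig,
    SyntheticRecord,
    generate_transcripts,
    make_read_set,
)

N_TRAIN = 3000
N_TEST = 1000
LENGTH_RANGE = (500, 2000)
MOTIF_DENSITY = 0.01
NOISE_RATES = {"sub_rate": 0.05, "ins_rate": 0.025, "del_rate": 0.025}


@dataclass
class Benchmark:
    """A train/test split with ground-truth-labeled test reads."""

    train_transcripts: list[SyntheticRecord]
    test_transcripts: list[SyntheticRecord]
    test_reads: list[SyntheticRecord]
    config: SyntheticConfig


def make_benchmark(
    seed: int,
    n_train: int = N_TRAIN,
    n_test: int = N_TEST,
    motif_density: float = MOTIF_DENSITY,
    motifs: tuple[str, ...] | None = None,
    length_range: tuple[int, int] = LENGTH_RANGE,
    noisy: bool = False,
) -> Benchmark:
    """Generate the benchmark split; ``noisy`` applies the 10% error channel
    to the test reads (training transcripts stay clean, mirroring training
    on an annotation and testing on noisy reads)."""
    kwargs = dict(
        n_seqs=n_train + n_test,
        length_range=length_range,
        motif_density=motif_density,
        seed=seed,
    )
    if motifs is not None:
        kwargs["motifs"] = motifs
    config = SyntheticConfig(**kwargs)
    transcripts = generate_transcripts(config)
    train, test = transcripts[:n_train], transcripts[n_train:]
    read_config = replace(
        config, seed=seed + 101, **(NOISE_RATES if noisy else {})
    )
    reads = make_read_set(test, read_config)
    return Benchmark(train, test, reads, config)


def train_benchmark_mlp(
    bench: Benchmark, seed: int, k_max: int = 4, **config_overrides
) -> models.TrainedModel:
    seqs, labels = models.make_balanced_training_set(
        bench.train_transcripts, seed=seed
    )
    config = models.MlpConfig(k_max=k_max, seed=seed, **config_overrides)
    return models.train_mlp(seqs, labels, config)


def train_benchmark_cnn(
    bench: Benchmark, seed: int, **config_overrides
) -> models.TrainedModel:
    seqs, labels = models.make_balanced_training_set(
        bench.train_transcripts, seed=seed
    )
    config = models.CnnConfig(seed=seed, **config_overrides)
    return models.train_cnn(seqs, labels, config)


def accuracy(model: models.TrainedModel, reads) -> float:
    return inference.evaluate(model, reads).accuracy


def trimmed_reads(reads, trim_n: int = 100):
    """Symmetrically end-trimmed copies of the test reads."""
    trimmed, _ = preprocess(reads, trim_n=trim_n, min_len=50)
    return trimmed


def simulated_vote_experiment(
    seed: int,
    n_transcripts: int = 300,
    cluster_sizes: tuple[int, int] = (5, 20),
    per_read_accuracy: float = 0.8,
) -> tuple[float, float]:
    """Majority-vote gain with simulated per-read calls of given accuracy.

    Clusters are orientation-homogeneous (strand-specific clustering);
    per-read predictions flip the truth independently with probability
    1 - per_read_accuracy.  Returns (uncorrected, corrected) accuracy.
    """
    config = SyntheticConfig(
        n_seqs=n_transcripts,
        length_range=(250, 400),
        reads_per_transcript=cluster_sizes,
        seed=seed,
    )
    reads = make_read_set(generate_transcripts(config), config)
    rng = np.random.default_rng(seed + 7)
    flip = {
        Orientation.FORWARD.value: Orientation.REVERSE.value,
        Orientation.REVERSE.value: Orientation.FORWARD.value,
    }
    truth = {r.read_id: r.label.value for r in reads}
    pred = {
        rid: lab if rng.random() < per_read_accuracy else flip[lab]
        for rid, lab in truth.items()
    }
    clusters = {r.read_id: r.cluster_id for r in reads}
    corrected = cluster_vote.majority_vote(pred, clusters)
    raw_acc = float(np.mean([pred[r] == truth[r] for r in truth]))
    vote_acc = float(np.mean([corrected[r] == truth[r] for r in truth]))
    return raw_acc, vote_acc
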