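"""The two orientation classifiers: definition, training, persistence.

Both models output the probability that an input sequence is *not* in the
native 5'-to-3' orientation (label 1 = reverse-complemented):

* the MLP takes a normalized k-mer frequency vector and ends in a single
  sigmoid unit, with five hidden layers and dropout after each;
* the CNN takes one-hot 500-nt windows through three convolution + pooling
  stages and three dense layers, ending in a 2-class softmax
  (column 0 = forward posterior, column 1 = reverse posterior).

Training sets are balanced by reverse-complementing either a random half of
the input sequences (relabeling them 1) or, optionally, all of them to
double the training input.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .features import (
    KmerSpec,
    WindowingSpec,
    kmer_frequency_vector,
    one_hot_windows,
    reverse_complement,
)
from .seqio import Orientation, SeqRecord

LABEL_CONVENTION = "score is the probability the sequence is NOT 5'-to-3'"
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class MlpConfig:
    """Multilayer perceptron on k-mer frequencies (5 hidden layers)."""

    k_max: int = 5
    hidden_sizes: tuple[int, ...] = (512, 256, 128, 64, 32)
    dropout_rate: float = 0.2
    epochs: int = 60
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 5:
            raise ValueError("the MLP has exactly 5 hidden layers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class CnnConfig:
    """CNN on one-hot windows: 3 conv, 3 pool, 3 dense layers.

    The default shape concentrates pattern detection in a wide first stage
    (32 motif-scanning filters, the ones later convertible to PWMs) and
    pools aggressively afterwards: coarse spatial resolution keeps the
    model from memorizing individual windows, which is what lets the conv
    filters converge on sequence features at moderate training-set sizes.
    The second/third convolutions act as channel mixers over the pooled
    feature map (network-in-network style 1-2 wide kernels).
    """

    conv_filters: tuple[int, ...] = (32, 64, 64)
    conv_widths: tuple[int, ...] = (9, 2, 1)
    pool_sizes: tuple[int, ...] = (61, 7, 1)
    dense_sizes: tuple[int, ...] = (64, 32)  # final dense(2, softmax) implied
    dropout_rate: float = 0.25
    window: int = 500
    stride: int = 250
    epochs: int = 80
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not len(self.conv_filters) == len(self.conv_widths) == len(self.pool_sizes) == 3:
            raise ValueError("the CNN has exactly 3 conv and 3 pooling layers")
        if len(self.dense_sizes) != 2:
            raise ValueError("the CNN has exactly 3 dense layers (last is the 2-class head)")

    @property
    def n_filters_layer1(self) -> int:
        return self.conv_filters[0]

    @property
    def windowing(self) -> WindowingSpec:
        return WindowingSpec(self.window, self.stride)


def make_balanced_training_set(
    records: Sequence[SeqRecord], double: bool = False, seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """Build a class-balanced (sequences, labels) training set.

    All records must carry an orientation label; REVERSE-labeled records are
    first normalized to forward by reverse-complementing them.  With
    ``double=False`` a seeded random half of the sequences is
    reverse-complemented and labeled 1; with ``double=True`` every sequence
    appears twice, once per orientation.  The output order is shuffled.
    """
    if not records:
        raise ValueError("empty training input")
    forward: list[str] = []
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.read_id!r} has no orientation label")
        seq = rec.seq
        if rec.label is Orientation.REVERSE:
            seq = reverse_complement(seq)
        forward.append(seq)
    rng = np.random.default_rng(seed)
    n = len(forward)
    if double:
        seqs = forward + [reverse_complement(s) for s in forward]
        labels = np.concatenate([np.zeros(n), np.ones(n)])
    else:
        flip = rng.choice(n, size=n // 2, replace=False)
        flip_set = set(flip.tolist())
        seqs = [
            reverse_complement(s) if i in flip_set else s
            for i, s in enumerate(forward)
        ]
        labels = np.array([1.0 if i in flip_set else 0.0 for i in range(n)])
    order = rng.permutation(len(seqs))
    return [seqs[i] for i in order], labels[order]


@dataclass
class TrainedModel:
    """A trained classifier plus the featurization it expects."""

    kind: str  # "mlp" | "cnn"
    network: _nn.Network
    config: MlpConfig | CnnConfig
    training_log: list = field(default_factory=list)
    label_convention: str = LABEL_CONVENTION

    @property
    def kmer_spec(self) -> KmerSpec:
        if self.kind != "mlp":
            raise ValueError("k-mer featurization applies to the MLP model only")
        return KmerSpec(self.config.k_max)

    @property
    def windowing(self) -> WindowingSpec:
        if self.kind != "cnn":
            raise ValueError("windowing applies to the CNN model only")
        return self.config.windowing

    def score_kmer_vectors(self, X: np.ndarray) -> np.ndarray:
        """Reverse-orientation probability per feature vector (MLP)."""
        if self.kind != "mlp":
            raise ValueError("not an MLP model")
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        expected = self.kmer_spec.n_features
        if X.shape[1] != expected:
            raise ValueError(
                f"feature vector length {X.shape[1]} does not match the model's "
                f"k_max={self.config.k_max} (expected {expected})"
            )
        return self.network.predict_proba(X)

    def window_posteriors(self, windows_onehot: np.ndarray) -> np.ndarray:
        """(n, 2) forward/reverse posteriors per one-hot window (CNN)."""
        if self.kind != "cnn":
            raise ValueError("not a CNN model")
        X = np.asarray(windows_onehot, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (4, self.config.window):
            raise ValueError(
                f"window batch shape {X.shape[1:]} != (4, {self.config.window})"
            )
        return self.network.predict_proba(X)

    def first_conv_layer(self) -> _nn.Conv1D:
        if self.kind != "cnn":
            raise ValueError("an MLP model has no convolutional filters")
        return self.network.layers[0]


def _build_mlp(config: MlpConfig, rng: np.random.Generator) -> _nn.Network:
    layers: list[_nn.Layer] = []
    n_in = KmerSpec(config.k_max).n_features
    for h in config.hidden_sizes:
        layers += [
            _nn.Dense(n_in, h, rng),
            _nn.ReLU(),
            _nn.Dropout(config.dropout_rate, rng),
        ]
        n_in = h
    layers.append(_nn.Dense(n_in, 1, rng, scale="glorot"))
    return _nn.Network(layers, head="sigmoid")


def _build_cnn(config: CnnConfig, rng: np.random.Generator) -> _nn.Network:
    layers: list[_nn.Layer] = []
    c_in, length = 4, config.window
    for c_out, width, pool in zip(
        config.conv_filters, config.conv_widths, config.pool_sizes
    ):
        layers += [_nn.Conv1D(c_in, c_out, width, rng), _nn.ReLU(), _nn.MaxPool1D(pool)]
        length = (length - width + 1) // pool
        c_in = c_out
    layers.append(_nn.Flatten())
    n_in = c_in * length
    for h in config.dense_sizes:
        layers += [
            _nn.Dense(n_in, h, rng),
            _nn.ReLU(),
            _nn.Dropout(config.dropout_rate, rng),
        ]
        n_in = h
    layers.append(_nn.Dense(n_in, 2, rng, scale="glorot"))
    return _nn.Network(layers, head="softmax")


def _check_two_classes(labels: np.ndarray) -> None:
    n_pos = int(labels.sum())
    if n_pos < 2 or len(labels) - n_pos < 2:
        raise ValueError("need at least 2 training examples per class")


def train_mlp(
    seqs: Sequence[str], labels: np.ndarray, config: MlpConfig | None = None
) -> TrainedModel:
    """Train the k-mer MLP on a balanced (sequences, labels) set."""
    config = config or MlpConfig()
    labels = np.asarray(labels, dtype=np.float64)
    _check_two_classes(labels)
    spec = KmerSpec(config.k_max)
    X = np.stack([kmer_frequency_vector(s, spec) for s in seqs]).astype(np.float32)
    rng = np.random.default_rng(config.seed)
    net = _build_mlp(config, rng)
    log: list = []
    net.fit(
        X,
        labels,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        patience=config.patience,
        rng=rng,
        log=log,
    )
    return TrainedModel("mlp", net, config, training_log=log)


def train_cnn(
    seqs: Sequence[str], labels: np.ndarray, config: CnnConfig | None = None
) -> TrainedModel:
    """Train the window CNN; every window of a sequence inherits its label."""
    config = config or CnnConfig()
    labels = np.asarray(labels, dtype=np.float64)
    _check_two_classes(labels)
    spec = config.windowing
    mats, ys = [], []
    for seq, lab in zip(seqs, labels):
        w = one_hot_windows(seq, spec)
        mats.append(w)
        ys.append(np.full(len(w), lab))
    X = np.concatenate(mats).astype(np.float32)
    y = np.concatenate(ys)
    rng = np.random.default_rng(config.seed)
    net = _build_cnn(config, rng)
    log: list = []
    net.fit(
        X,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        patience=config.patience,
        rng=rng,
        log=log,
    )
    return TrainedModel("cnn", net, config, training_log=log)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model as a directory: weights.npz + a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = model.network.get_weights()
    np.savez(path / "weights.npz", **{f"w{i:03d}": w for i, w in enumerate(weights)})
    sidecar = {
        "format_version": _FORMAT_VERSION,
        "kind": model.kind,
        "label_convention": model.label_convention,
        "config": dataclasses.asdict(model.config),
        "numpy_version": np.__version__,
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_model(path: str | Path, expect_kind: str | None = None) -> TrainedModel:
    """Load a saved model; predictions are bitwise-identical to pre-save."""
    path = Path(path)
    sidecar = json.loads((path / "model.json").read_text())
    if sidecar.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {sidecar.get('format_version')}")
    kind = sidecar["kind"]
    if expect_kind is not None and kind != expect_kind:
        raise ValueError(f"model at {path} is {kind!r}, expected {expect_kind!r}")
    cfg = sidecar["config"]
    rng = np.random.default_rng(0)
    if kind == "mlp":
        config = MlpConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()})
        net = _build_mlp(config, rng)
    elif kind == "cnn":
        config = CnnConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()})
        net = _build_cnn(config, rng)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    with np.load(path / "weights.npz") as npz:
        weights = [npz[k] for k in sorted(npz.files)]
    try:
        net.set_weights(weights)
    except ValueError as exc:
        raise ValueError(f"weights at {path} do not match a {kind} architecture: {exc}") from exc
    return TrainedModel(kind, net, config, label_convention=sidecar["label_convention"])
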