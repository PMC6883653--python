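"""Deterministic sequence featurization.

Two feature representations feed the two classifiers:

* normalized k-mer frequency vectors (all k from 1 to ``k_max``, default 5)
  for the multilayer perceptron, and
* one-hot encoded 500-nt sliding windows (stride 250) for the convolutional
  network.

For a fixed k the count of each k-mer (overlapping occurrences) is divided
by the total number of k-mers in a sequence of length L, i.e.
``frequency(kmer) = count(kmer) / (L - k + 1)``, so every order-k block of
the feature vector sums to 1 and the vector length is independent of L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq`` over the alphabet {A,C,G,T,N}.

    N maps to N.  Raises ``ValueError`` on any other symbol.
    """
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"cannot reverse-complement symbols {bad!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerSpec:
    """Featurization spec for the MLP: k-mer orders 1..k_max, A<C<G<T order."""

    k_max: int = 5

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    @property
    def n_features(self) -> int:
        return sum(4**k for k in range(1, self.k_max + 1))

    def block_slice(self, k: int) -> slice:
        """Index range of the order-k block inside the feature vector."""
        start = sum(4**j for j in range(1, k))
        return slice(start, start + 4**k)


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T} to integer codes 0..3."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(128, 255, dtype=np.uint8)
    for base, i in _BASE_INDEX.items():
        table[ord(base)] = i
    out = table[codes]
    if (out == 255).any():
        pos = int(np.argmax(out == 255))
        raise ValueError(f"unexpected symbol {seq[pos]!r} at position {pos}")
    return out.astype(np.int64)


def kmer_frequency_vector(seq: str, spec: KmerSpec | None = None) -> np.ndarray:
    """Normalized k-mer frequency vector for orders 1..k_max.

    Entries are indexed by (k, lexicographic k-mer); within each order the
    4^k frequencies sum to 1.  The sequence must contain no N (preprocessing
    guarantees this) and must be at least ``k_max`` long.
    """
    spec = spec or KmerSpec()
    if len(seq) < spec.k_max:
        raise ValueError(
            f"sequence of length {len(seq)} is shorter than k_max={spec.k_max}; "
            "filter short reads before featurization"
        )
    codes = encode_bases(seq)
    L = len(codes)
    out = np.zeros(spec.n_features, dtype=np.float64)
    idx = np.zeros(L, dtype=np.int64)  # rolling k-mer index, updated per k
    n_valid = L + 1
    for k in range(1, spec.k_max + 1):
        n_valid -= 1  # = L - k + 1
        idx = idx[: L - k + 1] * 4 + codes[k - 1 :]
        counts = np.bincount(idx, minlength=4**k)
        block = spec.block_slice(k)
        out[block] = counts / n_valid
    return out


def kmer_revcomp_permutation(spec: KmerSpec) -> np.ndarray:
    """Permutation p with featurize(rc(s)) == featurize(s)[p] for N-free s."""
    perm = np.empty(spec.n_features, dtype=np.int64)
    for k in range(1, spec.k_max + 1):
        block = spec.block_slice(k)
        idx = np.arange(4**k)
        rc = np.zeros_like(idx)
        rest = idx
        for _ in range(k):
            rc = rc * 4 + (3 - rest % 4)  # complement of last base, reversed order
            rest = rest // 4
        perm[block] = block.start + rc
    return perm


@dataclass(frozen=True)
class WindowingSpec:
    """CNN input windows: width 500 nt, stride 250 (250-nt overlap), N-padded."""

    window: int = 500
    stride: int = 250

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.window:
            raise ValueError("need 0 < stride <= window")


def windows(seq: str, spec: WindowingSpec | None = None) -> list[str]:
    """Overlapping windows of a sequence, right-padded with N to full width.

    Starts are 0, stride, 2*stride, ...; a non-zero start is emitted only
    while it is < L - overlap, so no window consists solely of bases already
    covered by the previous one.  Sequences shorter than one window yield a
    single right-padded window.
    """
    spec = spec or WindowingSpec()
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    overlap = spec.window - spec.stride
    starts = [0]
    s = spec.stride
    while s < L - overlap:
        starts.append(s)
        s += spec.stride
    return [seq[s : s + spec.window].ljust(spec.window, "N") for s in starts]


def n_windows(L: int, spec: WindowingSpec | None = None) -> int:
    spec = spec or WindowingSpec()
    if L <= spec.window:
        return 1
    return 1 + int(np.ceil((L - spec.window) / spec.stride))


def one_hot(window: str, spec: WindowingSpec | None = None) -> np.ndarray:
    """4 x W binary matrix (rows A,C,G,T); N columns are all-zero."""
    spec = spec or WindowingSpec()
    if len(window) != spec.window:
        raise ValueError(f"window length {len(window)} != {spec.window}")
    codes = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    out = np.zeros((4, spec.window), dtype=np.float32)
    for base, i in _BASE_INDEX.items():
        out[i, codes == ord(base)] = 1.0
    known = out.sum(axis=0) + (codes == ord("N"))
    if (known == 0).any():
        pos = int(np.argmax(known == 0))
        raise ValueError(f"unexpected symbol {window[pos]!r} at position {pos}")
    return out


def one_hot_windows(seq: str, spec: WindowingSpec | None = None) -> np.ndarray:
    """Stacked one-hot matrices for all windows of ``seq``: (n, 4, W)."""
    spec = spec or WindowingSpec()
    return np.stack([one_hot(w, spec) for w in windows(seq, spec)])
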