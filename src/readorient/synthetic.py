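"""Synthetic transcriptomes and noisy long reads with known orientation.

Real mRNA sequences carry strand-asymmetric signals (regulatory motifs,
compositional bias, a poly-A tail) that orientation classifiers exploit.
The generator emulates exactly that: forward-strand transcripts drawn from
a background base composition with non-overlapping k-mer motifs planted at
a configurable density, an optional geometric poly-A tail, an ONT-like
substitution/insertion/deletion error channel, 5' truncation mimicking
internal priming, and random reverse-complementation of reads with the
truth label recorded.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import ALPHABET, encode_bases, reverse_complement
from .seqio import Orientation, SeqRecord

# Ten fixed non-palindromic hexamers used as the default planted signal.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "TGCATG",
    "GGACTT",
    "ATCCGA",
    "CAGTTC",
    "TTAGGC",
    "GATTAC",
    "CCATAG",
    "ACGGTA",
    "TCTGGA",
    "AGCTCA",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the simulator.

    ``motif_density`` is the expected number of planted motifs per
    nucleotide (0.01 = one per 100 nt).  ``polya_mean`` is the mean of the
    geometric tail-length distribution (0 disables the tail).  Error rates
    are per base; indels have length 1.  ``truncation_5p_prob`` is the
    probability a read lost its 5' end (geometric length, mean
    ``truncation_mean``, capped so at least 250 nt remain).
    """

    n_seqs: int = 1000
    length_range: tuple[int, int] = (500, 2000)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    motif_density: float = 0.01
    polya_mean: float = 0.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    truncation_5p_prob: float = 0.0
    truncation_mean: float = 100.0
    reads_per_transcript: tuple[int, int] = (1, 1)
    revcomp_prob: float = 0.5
    cluster_by_strand: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")
        lo, hi = self.length_range
        if lo < 250 or hi < lo:
            raise ValueError("length_range must satisfy 250 <= min <= max")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or not math.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        for m in self.motifs:
            if not 4 <= len(m) <= 8 or set(m) - set(ALPHABET):
                raise ValueError(f"motif {m!r} must be a 4-8 nt string over ACGT")
        for name in ("motif_density", "sub_rate", "ins_rate", "del_rate",
                     "truncation_5p_prob", "revcomp_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo_r, hi_r = self.reads_per_transcript
        if lo_r < 1 or hi_r < lo_r:
            raise ValueError("reads_per_transcript must satisfy 1 <= min <= max")


@dataclass
class SyntheticRecord(SeqRecord):
    """A SeqRecord plus simulation truth."""

    cluster_id: str | None = None
    motif_positions: tuple[int, ...] = ()
    n_error_events: int = 0
    source_length: int = 0


def _plant_motifs(
    seq: np.ndarray, motifs: Sequence[str], density: float, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Overwrite background bases with motifs at non-overlapping positions.

    The number of insertions is Poisson(density * L); overlapping draws are
    resampled (bounded retries), so the realized count can fall slightly
    short at extreme densities.
    """
    L = len(seq)
    n = rng.poisson(density * L)
    occupied: list[tuple[int, int]] = []
    positions: list[int] = []
    for _ in range(n):
        motif = motifs[rng.integers(len(motifs))]
        w = len(motif)
        for _attempt in range(50):
            pos = int(rng.integers(0, L - w + 1))
            if all(pos + w <= s or pos >= e for s, e in occupied):
                seq[pos : pos + w] = encode_bases(motif)
                occupied.append((pos, pos + w))
                positions.append(pos)
                break
    return seq, tuple(sorted(positions))


def generate_transcripts(config: SyntheticConfig) -> list[SyntheticRecord]:
    """Forward-strand transcripts with planted motifs and optional poly-A."""
    rng = np.random.default_rng(config.seed)
    comp = np.asarray(config.base_composition, dtype=float)
    lo, hi = config.length_range
    out: list[SyntheticRecord] = []
    for i in range(config.n_seqs):
        L = int(rng.integers(lo, hi + 1))
        codes = rng.choice(4, size=L, p=comp)
        positions: tuple[int, ...] = ()
        if config.motifs and config.motif_density > 0:
            codes, positions = _plant_motifs(
                codes, config.motifs, config.motif_density, rng
            )
        seq = _BASES[codes].tobytes().decode("ascii")
        if config.polya_mean > 0:
            tail = int(rng.geometric(1.0 / config.polya_mean))
            seq += "A" * tail
        out.append(
            SyntheticRecord(
                read_id=f"t{i:05d}",
                seq=seq,
                label=Orientation.FORWARD,
                cluster_id=f"t{i:05d}",
                motif_positions=positions,
                source_length=len(seq),
            )
        )
    return out


def _error_channel(
    codes: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Apply per-base substitutions and length-1 indels; count the events."""
    n_events = 0
    if config.del_rate > 0:
        keep = rng.random(len(codes)) >= config.del_rate
        n_events += int((~keep).sum())
        codes = codes[keep]
    else:
        codes = codes.copy()
    if config.sub_rate > 0 and len(codes):
        sub = rng.random(len(codes)) < config.sub_rate
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
        n_events += int(sub.sum())
    if config.ins_rate > 0 and len(codes):
        ins = rng.random(len(codes)) < config.ins_rate
        if ins.any():
            counts = 1 + ins.astype(np.int64)
            starts = np.cumsum(counts) - counts
            out = np.empty(int(counts.sum()), dtype=codes.dtype)
            out[starts] = codes
            out[starts[ins] + 1] = rng.integers(0, 4, size=int(ins.sum()))
            codes = out
            n_events += int(ins.sum())
    return codes, n_events


def make_read_set(
    transcripts: Sequence[SyntheticRecord], config: SyntheticConfig
) -> list[SyntheticRecord]:
    """Noisy reads from transcripts, each randomly reverse-complemented.

    Per transcript, a uniform number of reads in ``reads_per_transcript``
    is drawn.  Each read is optionally 5'-truncated, run through the error
    channel, then reverse-complemented with probability ``revcomp_prob``;
    the truth label records the final strand.  With ``cluster_by_strand``
    (the default) a cluster is one (transcript, strand) pair, emulating the
    strand-specific clusters minimizer-based read clusterers produce — the
    regime in which a majority vote over a cluster is meaningful; otherwise
    all reads of a transcript share a cluster regardless of strand.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo_r, hi_r = config.reads_per_transcript
    reads: list[SyntheticRecord] = []
    for tr in transcripts:
        n_reads = int(rng.integers(lo_r, hi_r + 1))
        base_codes = encode_bases(tr.seq)
        for j in range(n_reads):
            codes = base_codes
            if config.truncation_5p_prob > 0 and rng.random() < config.truncation_5p_prob:
                cut = int(rng.geometric(1.0 / config.truncation_mean))
                cut = min(cut, max(len(codes) - 250, 0))
                codes = codes[cut:]
            codes, n_events = _error_channel(codes, config, rng)
            seq = _BASES[codes].tobytes().decode("ascii")
            if rng.random() < config.revcomp_prob:
                seq = reverse_complement(seq)
                label = Orientation.REVERSE
            else:
                label = Orientation.FORWARD
            cluster = tr.cluster_id
            if config.cluster_by_strand and cluster is not None:
                cluster = f"{cluster}:{'+' if label is Orientation.FORWARD else '-'}"
            reads.append(
                SyntheticRecord(
                    read_id=f"{tr.read_id}_r{j}",
                    seq=seq,
                    label=label,
                    cluster_id=cluster,
                    n_error_events=n_events,
                    source_length=len(tr.seq),
                )
            )
    return reads


def write_truth(records: Sequence[SyntheticRecord], path: str | Path) -> None:
    """TSV of read_id, true orientation, cluster_id (one row per read)."""
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_label\tcluster_id\n")
        for rec in records:
            if rec.label is None:
                raise ValueError(f"record {rec.read_id!r} has no truth label")
            fh.write(f"{rec.read_id}\t{rec.label.value}\t{rec.cluster_id or ''}\n")


def read_truth(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Parse a truth TSV back into (read -> label, read -> cluster) maps."""
    labels: dict[str, str] = {}
    clusters: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing truth header")
        for line in fh:
            read_id, label, cluster = line.rstrip("\n").split("\t")
            labels[read_id] = label
            if cluster:
                clusters[read_id] = cluster
    return labels, clusters


def write_cluster_table(records: Sequence[SyntheticRecord], path: str | Path) -> None:
    """Cluster TSV (cluster_id <tab> read_id) for the majority-vote module."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.cluster_id is not None:
                fh.write(f"{rec.cluster_id}\t{rec.read_id}\n")
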