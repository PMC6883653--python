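"""Sequence I/O: FASTA/FASTQ reading, preprocessing, label construction.

Labeled datasets come from three kinds of sources:

* ``ANNOTATION`` — transcript sequences from an annotation, taken to be in
  the correct 5'-to-3' orientation;
* ``EXPERIMENTAL`` — direct-RNA sequencing reads, inherently 5'-to-3'
  (U is converted to T on read);
* ``MAPPED`` — cDNA reads whose orientation is derived from a minimap2 PAF
  alignment against 5'-to-3' transcripts, keeping only uniquely-mapping
  reads at maximum mapping quality.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .features import reverse_complement


class Orientation(enum.Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


class SourceKind(enum.Enum):
    ANNOTATION = "annotation"
    EXPERIMENTAL = "experimental"
    MAPPED = "mapped"


@dataclass
class SeqRecord:
    """One read or transcript.

    ``seq`` is an uppercase nucleotide string; ``qual`` (FASTQ only) has the
    same length as ``seq``; ``label`` is the known 5'-to-3' orientation when
    available.
    """

    read_id: str
    seq: str
    qual: str | None = None
    label: Orientation | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.read_id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )


class ParseError(ValueError):
    pass


def _detect_format(path: str | Path) -> str:
    with open(path, "rb") as fh:
        first = fh.read(1)
    if first == b">":
        return "fasta"
    if first == b"@":
        return "fastq"
    raise ParseError(f"{path}: cannot auto-detect format from first byte {first!r}")


def read_sequences(path: str | Path, format: str = "auto") -> list[SeqRecord]:
    """Read FASTA or FASTQ into SeqRecords, preserving file order.

    Sequences are uppercased and U is converted to T unconditionally
    (direct-RNA reads are reported over the RNA alphabet; the conversion is
    harmless for DNA input).
    """
    fmt = format.lower()
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = str(rec.seq).upper().replace("U", "T")
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            records.append(SeqRecord(rec.id, seq, qual, description=rec.description))
    except ValueError as exc:
        at = records[-1].read_id if records else "<first record>"
        raise ParseError(f"{path}: malformed record after {at!r}: {exc}") from exc
    return records


@dataclass
class DiscardLog:
    """Book-keeping for reads dropped during preprocessing."""

    n_input: int = 0
    n_contains_n: int = 0
    n_too_short: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def preprocess(
    records: Iterable[SeqRecord], trim_n: int = 0, min_len: int = 50
) -> tuple[list[SeqRecord], DiscardLog]:
    """Discard N-containing reads, trim ends symmetrically, drop short reads.

    ``trim_n`` bases are removed from both ends of every surviving read.
    Reads whose post-trim length falls below ``min_len`` are dropped.
    """
    if trim_n < 0:
        raise ValueError("trim_n must be >= 0")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    log = DiscardLog()
    out: list[SeqRecord] = []
    for rec in records:
        log.n_input += 1
        if "N" in rec.seq:
            log.n_contains_n += 1
            continue
        seq = rec.seq[trim_n : len(rec.seq) - trim_n] if trim_n else rec.seq
        if len(seq) < min_len:
            log.n_too_short += 1
            continue
        qual = rec.qual
        if qual is not None and trim_n:
            qual = qual[trim_n : len(rec.qual) - trim_n]
        out.append(replace(rec, seq=seq, qual=qual))
    log.n_kept = len(out)
    return out, log


@dataclass(frozen=True)
class MappedLabelFilter:
    """Criteria for accepting a PAF alignment as an orientation label."""

    min_mapq: int = 60
    require_unique: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_mapq <= 60:
            raise ValueError("min_mapq must be in [0, 60]")


def parse_paf_labels(
    paf_path: str | Path, filter: MappedLabelFilter | None = None
) -> tuple[dict[str, Orientation], Counter]:
    """Derive read orientations from a PAF alignment of reads to transcripts.

    A read is labeled iff it has exactly one PAF record (uniquely mapping
    under secondary-suppressed alignment) with MAPQ >= ``min_mapq``.  Since
    the targets are 5'-to-3' transcripts, strand '+' means the read is
    FORWARD and '-' means REVERSE.  Returns the label mapping plus exclusion
    counts keyed by reason (``low_mapq``, ``multimapping``).
    """
    filter = filter or MappedLabelFilter()
    hits: dict[str, list[tuple[str, int]]] = {}
    with open(paf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise ParseError(
                    f"{paf_path}:{lineno}: expected >= 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            strand = cols[4]
            if strand not in "+-":
                raise ParseError(
                    f"{paf_path}:{lineno}: unknown strand symbol {strand!r}"
                )
            try:
                mapq = int(cols[11])
            except ValueError as exc:
                raise ParseError(f"{paf_path}:{lineno}: bad MAPQ {cols[11]!r}") from exc
            hits.setdefault(cols[0], []).append((strand, mapq))
    labels: dict[str, Orientation] = {}
    excluded: Counter = Counter()
    for read_id, recs in hits.items():
        if filter.require_unique and len(recs) > 1:
            excluded["multimapping"] += 1
            continue
        strand, mapq = recs[0]
        if mapq < filter.min_mapq:
            excluded["low_mapq"] += 1
            continue
        labels[read_id] = Orientation.FORWARD if strand == "+" else Orientation.REVERSE
    return labels, excluded


def build_labeled_dataset(
    source: SourceKind,
    seq_path: str | Path,
    paf_path: str | Path | None = None,
    filter: MappedLabelFilter | None = None,
    format: str = "auto",
) -> list[SeqRecord]:
    """Read sequences and attach orientation labels according to the source.

    Annotation transcripts and direct-RNA reads are all FORWARD by
    definition; mapped reads take their label from the PAF, and reads the
    PAF does not label are dropped.
    """
    records = read_sequences(seq_path, format=format)
    if source in (SourceKind.ANNOTATION, SourceKind.EXPERIMENTAL):
        for rec in records:
            rec.label = Orientation.FORWARD
        return records
    if paf_path is None:
        raise ValueError("MAPPED source requires a PAF path")
    labels, _excluded = parse_paf_labels(paf_path, filter)
    out = []
    for rec in records:
        if rec.read_id in labels:
            rec.label = labels[rec.read_id]
            out.append(rec)
    return out


def write_sequences(
    records: Sequence[SeqRecord], out_path: str | Path, format: str = "fasta"
) -> None:
    """Write records as-is (no reorientation, no header annotation)."""
    fmt = format.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with open(out_path, "w") as fh:
        for rec in records:
            if fmt == "fasta":
                fh.write(f">{rec.read_id}\n{rec.seq}\n")
            else:
                qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
                fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{qual}\n")


def _annotate_header(read_id: str, score: float, flipped: bool) -> str:
    return f"{read_id} ro_score={score:.6g} ro_flipped={int(flipped)}"


def write_oriented(
    records: Sequence[SeqRecord],
    scores: Sequence[float],
    out_path: str | Path,
    format: str = "fasta",
    threshold: float = 0.5,
) -> int:
    """Write reads in predicted 5'-to-3' orientation.

    A read whose score (probability of being reversed) is strictly greater
    than ``threshold`` is written reverse-complemented, with its quality
    string reversed when present.  Headers carry the score and a flipped
    flag after the original id token.  Returns the number of flipped reads.
    """
    if len(records) != len(scores):
        raise ValueError("need exactly one score per record")
    fmt = format.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    n_flipped = 0
    with open(out_path, "w") as fh:
        for rec, score in zip(records, scores):
            flip = score > threshold
            seq = reverse_complement(rec.seq) if flip else rec.seq
            n_flipped += flip
            header = _annotate_header(rec.read_id, score, flip)
            if fmt == "fasta":
                fh.write(f">{header}\n{seq}\n")
            else:
                qual = rec.qual if rec.qual is not None else "I" * len(seq)
                if flip:
                    qual = qual[::-1]
                fh.write(f"@{header}\n{seq}\n+\n{qual}\n")
    return n_flipped
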