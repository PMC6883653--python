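"""Motif extraction from first-layer CNN filters.

Each first-layer filter is scanned over the one-hot windows of a probe
sequence set; every position whose pre-pooling convolution output (after
bias, before pooling) is strictly positive contributes the aligned
filter-width input subsequence.  The collected subsequences per filter are
stacked into a position weight matrix, which can be written in MEME minimal
motif format for downstream comparison (e.g. TOMTOM against a motif
database).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .features import ALPHABET, one_hot, windows
from .models import TrainedModel

_ROW = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class PWM:
    """Position weight matrix: 4 x w probabilities (rows A,C,G,T)."""

    matrix: np.ndarray
    n_sites: int
    filter_id: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x w")
        if self.n_sites < 1:
            raise ValueError("a PWM needs at least one contributing site")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        """Maximum-probability string (ties broken by A<C<G<T order)."""
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))


@dataclass
class MotifSet:
    pwms: list[PWM]

    def __post_init__(self) -> None:
        ids = [p.filter_id for p in self.pwms]
        if len(set(ids)) != len(ids):
            raise ValueError("filter_ids must be unique")

    def __len__(self) -> int:
        return len(self.pwms)

    def __iter__(self):
        return iter(self.pwms)


def collect_activated_subsequences(
    model: TrainedModel,
    sequences: Iterable[str],
    batch_size: int = 256,
) -> dict[str, list[str]]:
    """Per-filter subsequences at strictly positive first-layer activations.

    Subsequences overlapping the N-padding of a window are skipped (padding
    carries no sequence signal).  Raises for an MLP model, which has no
    convolutional filters.
    """
    conv = model.first_conv_layer()
    width = conv.width
    spec = model.windowing
    sites: dict[str, list[str]] = {
        f"filter_{i}": [] for i in range(conv.c_out)
    }
    window_strings = [w for seq in sequences for w in windows(seq, spec)]
    for start in range(0, len(window_strings), batch_size):
        chunk = window_strings[start : start + batch_size]
        x = np.stack([one_hot(w, spec) for w in chunk])
        acts = conv.forward(x, train=False)  # (B, c_out, L_out)
        for b, wstr in enumerate(chunk):
            pos_f, pos_p = np.nonzero(acts[b] > 0)
            for f, p in zip(pos_f, pos_p):
                sub = wstr[p : p + width]
                if "N" in sub:
                    continue
                sites[f"filter_{f}"].append(sub)
    return sites


def filters_to_pwms(
    sites_per_filter: dict[str, list[str]], pseudocount: float = 0.0
) -> MotifSet:
    """Convert per-filter subsequence lists to PWMs.

    Column j of a filter's PWM is (base counts at position j + pseudocount)
    / (n_sites + 4 * pseudocount).  Filters with no contributing sites are
    dropped.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    pwms = []
    for filter_id, sites in sites_per_filter.items():
        if not sites:
            continue
        w = len(sites[0])
        counts = np.zeros((4, w), dtype=np.float64)
        for site in sites:
            for j, base in enumerate(site):
                counts[_ROW[base], j] += 1
        matrix = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
        pwms.append(PWM(matrix, n_sites=len(sites), filter_id=filter_id))
    return MotifSet(pwms)


def write_meme(
    motifset: MotifSet,
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write motifs in MEME minimal format (TOMTOM-consumable)."""
    if not len(motifset):
        raise ValueError("empty motif set")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for pwm in motifset:
            fh.write(f"MOTIF {pwm.filter_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {pwm.n_sites} E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" " + " ".join(f"{p:.6f}" for p in col) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> MotifSet:
    """Parse a MEME minimal motif file back into a MotifSet.

    Columns are renormalized to absorb the fixed-precision rounding of the
    text format.
    """
    pwms: list[PWM] = []
    name, n_sites, rows = None, 1, []

    def flush():
        nonlocal name, rows
        if name is not None and rows:
            matrix = np.array(rows, dtype=np.float64).T
            matrix = matrix / matrix.sum(axis=0, keepdims=True)
            pwms.append(PWM(matrix, n_sites=n_sites, filter_id=name))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                parts = line.split("nsites=")
                n_sites = int(parts[1].split()[0]) if len(parts) > 1 else 1
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                rows.append([float(x) for x in line.split()])
    flush()
    return MotifSet(pwms)
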