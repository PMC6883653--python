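"""Majority-vote correction of per-read orientation calls within clusters.

Reads from the same molecule (e.g. an IsONclust cluster) share a true
orientation, so the per-read calls can be pooled: if more than half of a
cluster's reads are predicted FORWARD, every read in the cluster is set
FORWARD; otherwise (including an exact 50% tie) every read is set REVERSE.
Reads not present in the clustering pass through unchanged.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Mapping

from .seqio import Orientation, ParseError

FORWARD = Orientation.FORWARD.value
REVERSE = Orientation.REVERSE.value


def parse_clusters(path: str | Path, read_id_first: bool = False) -> dict[str, str]:
    """Parse a two-column TSV of cluster assignments into read_id -> cluster.

    The default column order is ``cluster_id <tab> read_id`` (IsONclust
    style); pass ``read_id_first=True`` for the transposed layout.  A read
    assigned to two clusters is an error.
    """
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            read_id, cluster = (cols[0], cols[1]) if read_id_first else (cols[1], cols[0])
            if read_id in assignment:
                raise ParseError(
                    f"{path}:{lineno}: read {read_id!r} assigned to both "
                    f"cluster {assignment[read_id]!r} and {cluster!r}"
                )
            assignment[read_id] = cluster
    return assignment


def majority_vote(
    pred_labels: Mapping[str, str], clusters: Mapping[str, str]
) -> dict[str, str]:
    """Set every read in a cluster to the cluster's majority orientation.

    The rule is strict: FORWARD wins only with > 50% of the cluster's
    predicted labels; at exactly 50% (a tie) the whole cluster is set
    REVERSE.  Unclustered reads keep their per-read prediction.
    """
    members: dict[str, list[str]] = {}
    for read_id, label in pred_labels.items():
        if label not in (FORWARD, REVERSE):
            raise ValueError(f"read {read_id!r}: unexpected label {label!r}")
        cluster = clusters.get(read_id)
        if cluster is not None:
            members.setdefault(cluster, []).append(read_id)
    corrected = dict(pred_labels)
    for cluster, reads in members.items():
        n_forward = sum(1 for r in reads if pred_labels[r] == FORWARD)
        winner = FORWARD if n_forward > 0.5 * len(reads) else REVERSE
        for r in reads:
            corrected[r] = winner
    return corrected


def cluster_accuracy_profile(
    pred_labels: Mapping[str, str],
    true_labels: Mapping[str, str],
    clusters: Mapping[str, str],
    min_size: int = 3,
) -> tuple[dict[str, float], Counter]:
    """Per-cluster fraction of correctly predicted reads, plus a histogram.

    Returns (cluster -> proportion correct, Counter over proportions) for
    clusters with at least ``min_size`` reads (default 3, i.e. > 2 reads).
    """
    members: dict[str, list[str]] = {}
    for read_id in pred_labels:
        cluster = clusters.get(read_id)
        if cluster is not None:
            members.setdefault(cluster, []).append(read_id)
    proportions: dict[str, float] = {}
    for cluster, reads in members.items():
        if len(reads) < min_size:
            continue
        missing = [r for r in reads if r not in true_labels]
        if missing:
            raise ValueError(f"cluster {cluster!r}: no true label for {missing[0]!r}")
        correct = sum(1 for r in reads if pred_labels[r] == true_labels[r])
        proportions[cluster] = correct / len(reads)
    return proportions, Counter(proportions.values())
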