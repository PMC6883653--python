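"""Prediction and evaluation.

A read's score is the probability that it is not in 5'-to-3' orientation.
The decision rule is fixed: a read is called REVERSE iff its score is
strictly greater than the threshold (default 0.5); a score exactly at the
threshold is FORWARD.  For the CNN the score comes from averaging the
per-window posteriors of each orientation independently and taking the
orientation with the greatest mean.

Evaluation treats REVERSE as the positive class and reports precision,
recall, F1 and the read count, plus macro-averages over the two classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqio
from .features import kmer_frequency_vector, one_hot_windows
from .models import TrainedModel
from .seqio import Orientation, SeqRecord

UNDECIDED = "UNDECIDED"


@dataclass(frozen=True)
class PredictionConfig:
    threshold: float = 0.5


def cnn_read_posterior(model: TrainedModel, record: SeqRecord) -> tuple[float, float]:
    """Mean (forward, reverse) posterior over all windows of one read."""
    post = model.window_posteriors(one_hot_windows(record.seq, model.windowing))
    mean = post.mean(axis=0)
    return float(mean[0]), float(mean[1])


def score_reads(model: TrainedModel, records: Sequence[SeqRecord]) -> np.ndarray:
    """Reverse-orientation score per read; NaN where a read is unscorable.

    MLP: reads shorter than k_max cannot be featurized.  CNN: empty reads.
    Unscorable reads are reported as UNDECIDED downstream.
    """
    scores = np.full(len(records), np.nan)
    if model.kind == "mlp":
        k_max = model.config.k_max
        ok = [i for i, r in enumerate(records) if len(r.seq) >= k_max]
        if ok:
            spec = model.kmer_spec
            X = np.stack(
                [kmer_frequency_vector(records[i].seq, spec) for i in ok]
            ).astype(np.float32)
            scores[ok] = model.score_kmer_vectors(X)
    else:
        spans: list[tuple[int, int, int]] = []  # (record idx, start, stop)
        mats = []
        pos = 0
        for i, rec in enumerate(records):
            if not rec.seq:
                continue
            w = one_hot_windows(rec.seq, model.windowing)
            spans.append((i, pos, pos + len(w)))
            mats.append(w)
            pos += len(w)
        if mats:
            post = model.window_posteriors(np.concatenate(mats))
            for i, start, stop in spans:
                scores[i] = post[start:stop, 1].mean()
    return scores


def score_read(model: TrainedModel, record: SeqRecord) -> float:
    """Score one read (NaN if it cannot be featurized)."""
    return float(score_reads(model, [record])[0])


def decide(score: float, threshold: float = 0.5) -> str:
    if math.isnan(score):
        return UNDECIDED
    return Orientation.REVERSE.value if score > threshold else Orientation.FORWARD.value


def predict_orientations(
    model: TrainedModel,
    records: Sequence[SeqRecord],
    config: PredictionConfig | None = None,
    out_path: str | Path | None = None,
    out_format: str = "fasta",
) -> pd.DataFrame:
    """Score every read and optionally write the re-oriented sequence file.

    Returns a table with columns read_id, score, predicted_label, flipped.
    """
    config = config or PredictionConfig()
    scores = score_reads(model, records)
    labels = [decide(s, config.threshold) for s in scores]
    flipped = [int(lab == Orientation.REVERSE.value) for lab in labels]
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "score": scores,
            "predicted_label": labels,
            "flipped": flipped,
        }
    )
    if out_path is not None:
        seqio.write_oriented(
            records, list(scores), out_path, format=out_format, threshold=config.threshold
        )
    return df


@dataclass
class MetricsReport:
    """Precision/recall/F1 with REVERSE as the positive class."""

    precision: float
    recall: float
    f1: float
    n_reads: int
    tp: int
    fp: int
    fn: int
    tn: int
    undefined_precision: bool = False
    undefined_recall: bool = False
    n_unscored: int = 0
    per_group: pd.DataFrame | None = None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_reads if self.n_reads else float("nan")

    @property
    def macro_precision(self) -> float:
        return 0.5 * (self.precision + _safe_div(self.tn, self.tn + self.fn))

    @property
    def macro_recall(self) -> float:
        return 0.5 * (self.recall + _safe_div(self.tn, self.tn + self.fp))

    @property
    def macro_f1(self) -> float:
        p_f = _safe_div(self.tn, self.tn + self.fn)
        r_f = _safe_div(self.tn, self.tn + self.fp)
        f1_f = _safe_div(2 * p_f * r_f, p_f + r_f)
        return 0.5 * (self.f1 + f1_f)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n_reads": self.n_reads,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "undefined_precision": self.undefined_precision,
            "undefined_recall": self.undefined_recall,
            "n_unscored": self.n_unscored,
        }

    def summary(self) -> str:
        lines = [
            "orientation prediction metrics (positive class = REVERSE)",
            f"  reads evaluated : {self.n_reads}  (unscored: {self.n_unscored})",
            f"  accuracy        : {self.accuracy:.4f}",
            f"  precision       : {self.precision:.4f}"
            + ("  [undefined, no positive predictions]" if self.undefined_precision else ""),
            f"  recall          : {self.recall:.4f}"
            + ("  [undefined, no positive labels]" if self.undefined_recall else ""),
            f"  F1              : {self.f1:.4f}",
            f"  macro P/R/F1    : {self.macro_precision:.4f} / "
            f"{self.macro_recall:.4f} / {self.macro_f1:.4f}",
            f"  confusion       : TP={self.tp} FP={self.fp} FN={self.fn} TN={self.tn}",
        ]
        return "\n".join(lines)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def compute_metrics(
    true_labels: Sequence[str | Orientation],
    pred_labels: Sequence[str | Orientation],
) -> MetricsReport:
    """Confusion-matrix metrics from parallel label lists."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("label lists differ in length")
    if not true_labels:
        raise ValueError("no labeled records to evaluate")
    rev = Orientation.REVERSE.value
    t = [x.value if isinstance(x, Orientation) else x for x in true_labels]
    p = [x.value if isinstance(x, Orientation) else x for x in pred_labels]
    tp = sum(1 for a, b in zip(t, p) if a == rev and b == rev)
    fp = sum(1 for a, b in zip(t, p) if a != rev and b == rev)
    fn = sum(1 for a, b in zip(t, p) if a == rev and b != rev)
    tn = sum(1 for a, b in zip(t, p) if a != rev and b != rev)
    undef_p = (tp + fp) == 0
    undef_r = (tp + fn) == 0
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        n_reads=len(t),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        undefined_precision=undef_p,
        undefined_recall=undef_r,
    )


def evaluate(
    model: TrainedModel,
    records: Sequence[SeqRecord],
    config: PredictionConfig | None = None,
) -> MetricsReport:
    """Predict orientations for labeled reads and compare with the labels.

    Reads that cannot be featurized are excluded from the confusion matrix
    and counted in ``n_unscored``.
    """
    config = config or PredictionConfig()
    if any(r.label is None for r in records):
        raise ValueError("evaluate requires labeled records")
    if not records:
        raise ValueError("no labeled records to evaluate")
    scores = score_reads(model, records)
    keep = ~np.isnan(scores)
    true = [records[i].label for i in range(len(records)) if keep[i]]
    pred = [decide(scores[i], config.threshold) for i in range(len(records)) if keep[i]]
    report = compute_metrics(true, pred)
    report.n_unscored = int((~keep).sum())
    return report


def metrics_by_group(
    pred_labels: Mapping[str, str],
    true_labels: Mapping[str, str | Orientation],
    group_map: Mapping[str, str] | None = None,
    min_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of correct predictions per group (e.g. transcript type).

    Reads without a group fall under "ungrouped".  Returns (main, full)
    tables; the main table keeps only groups with more than ``min_n`` reads.
    """
    group_map = group_map or {}
    rows: dict[str, list[int]] = {}
    for read_id, pred in pred_labels.items():
        if read_id not in true_labels:
            continue
        truth = true_labels[read_id]
        truth = truth.value if isinstance(truth, Orientation) else truth
        group = group_map.get(read_id, "ungrouped")
        rows.setdefault(group, []).append(int(pred == truth))
    full = pd.DataFrame(
        [
            {"group": g, "n": len(v), "fraction_correct": sum(v) / len(v)}
            for g, v in sorted(rows.items())
        ],
        columns=["group", "n", "fraction_correct"],
    )
    main = full[full["n"] > min_n].reset_index(drop=True)
    return main, full
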