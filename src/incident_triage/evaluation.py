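"""Confusion matrices, per-class precision/recall/F, micro/macro averages.

Micro-averaged measures pool true/false positives and negatives over all
classes; macro averages are unweighted means of the per-class values. With
single-label complete predictions the micro precision, recall and F
coincide. Degenerate 0/0 cells are defined as 0 and logged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ensemble import LabelScheme

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "average_metrics",
    "select_best",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """l x l gold-vs-predicted counts (rows = gold, cols = predicted)."""

    scheme: LabelScheme
    counts: np.ndarray
    normalized: bool = False

    def tp(self, label: str) -> int:
        i = self.scheme.labels.index(label)
        return int(self.counts[i, i])

    def fp(self, label: str) -> int:
        i = self.scheme.labels.index(label)
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, label: str) -> int:
        i = self.scheme.labels.index(label)
        return int(self.counts[i, :].sum() - self.counts[i, i])

    def tn(self, label: str) -> int:
        return int(self.counts.sum()) - self.tp(label) - self.fp(label) - self.fn(label)

    def save_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["gold\\pred", *self.scheme.labels])
            for i, lab in enumerate(self.scheme.labels):
                writer.writerow([lab, *self.counts[i].tolist()])


@dataclass(frozen=True)
class MetricsReport:
    per_class: Mapping[str, tuple[float, float, float]]  # label -> (P, R, F)
    micro: tuple[float, float, float]
    macro: tuple[float, float, float]

    @property
    def micro_f(self) -> float:
        return self.micro[2]

    @property
    def macro_f(self) -> float:
        return self.macro[2]

    def save_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "precision", "recall", "f_score"])
            for lab, (p, r, f) in self.per_class.items():
                writer.writerow([lab, f"{p:.6f}", f"{r:.6f}", f"{f:.6f}"])
            writer.writerow(["micro", *(f"{v:.6f}" for v in self.micro)])
            writer.writerow(["macro", *(f"{v:.6f}" for v in self.macro)])


def confusion_matrix(
    gold: Sequence[str],
    pred: Sequence[str],
    scheme: LabelScheme,
    normalized: bool = False,
) -> ConfusionMatrix:
    if len(gold) != len(pred):
        raise ValueError(f"gold/pred length mismatch: {len(gold)} vs {len(pred)}")
    idx = {lab: i for i, lab in enumerate(scheme.labels)}
    counts = np.zeros((scheme.l, scheme.l), dtype=float)
    for g, p in zip(gold, pred):
        if g not in idx or p not in idx:
            raise ValueError(f"label outside the scheme: gold={g!r}, pred={p!r}")
        counts[idx[g], idx[p]] += 1
    if normalized:
        row_sums = counts.sum(axis=1, keepdims=True)
        counts = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    else:
        counts = counts.astype(int)
    return ConfusionMatrix(scheme=scheme, counts=counts, normalized=normalized)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp + fp == 0:
        logger.debug("0/0 precision defined as 0")
        p = 0.0
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        logger.debug("0/0 recall defined as 0")
        r = 0.0
    else:
        r = tp / (tp + fn)
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, tuple[float, float, float]]:
    if cm.normalized:
        raise ValueError("per-class metrics require an unnormalized confusion matrix")
    return {lab: _prf(cm.tp(lab), cm.fp(lab), cm.fn(lab)) for lab in cm.scheme.labels}


def average_metrics(cm: ConfusionMatrix) -> MetricsReport:
    if cm.normalized:
        raise ValueError("averaged metrics require an unnormalized confusion matrix")
    per_class = per_class_metrics(cm)
    tp = sum(cm.tp(lab) for lab in cm.scheme.labels)
    fp = sum(cm.fp(lab) for lab in cm.scheme.labels)
    fn = sum(cm.fn(lab) for lab in cm.scheme.labels)
    micro = _prf(tp, fp, fn)
    vals = np.array(list(per_class.values()))
    macro = (float(vals[:, 0].mean()), float(vals[:, 1].mean()), float(vals[:, 2].mean()))
    return MetricsReport(per_class=per_class, micro=micro, macro=macro)


def plot_confusion_heatmap(cm: ConfusionMatrix, path: str | Path) -> None:
    """Row-normalized confusion heatmap (warmer = more of the gold row)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = np.asarray(cm.counts, dtype=float)
    if not cm.normalized:
        row_sums = counts.sum(axis=1, keepdims=True)
        counts = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * cm.scheme.l, 0.8 + 0.6 * cm.scheme.l))
    im = ax.imshow(counts, cmap="YlOrRd", vmin=0, vmax=1)
    ax.set_xticks(range(cm.scheme.l), cm.scheme.labels, rotation=45, ha="right")
    ax.set_yticks(range(cm.scheme.l), cm.scheme.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("gold")
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def select_best(results: Sequence[tuple[object, MetricsReport]]) -> object:
    """Configuration with maximal micro-F; ties by macro-F, then input order."""
    if not results:
        raise ValueError("cannot select from an empty result list")
    best_cfg, best_key = None, None
    for order, (cfg, report) in enumerate(results):
        key = (-report.micro_f, -report.macro_f, order)
        if best_key is None or key < best_key:
            best_cfg, best_key = cfg, key
    return best_cfg
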