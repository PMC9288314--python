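"""Confusion-matrix metrics, splits, cross-validation and repeated runs.

Death is the positive class (label 1). Accuracy, recall, precision and F1
follow the usual confusion-matrix definitions; across-run stability is the
population variance of per-run accuracies. Splitting is stratified: with a
~13-sample test set an unstratified draw can lose a class entirely, leaving
the metrics undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .fusion import FusedDataset

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics",
           "run_variance", "split_8_2", "five_fold", "repeated_experiment"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; death (1) is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass
class MetricsReport:
    """Scalar metrics of one run plus optional across-run aggregation.

    ``flags`` names any metric whose defining ratio had a zero denominator
    and was therefore reported as 0.
    """

    accuracy: float
    recall: float
    precision: float
    f1: float
    flags: list[str] = field(default_factory=list)
    per_run_accuracies: list[float] = field(default_factory=list)
    variance: float = 0.0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "recall": self.recall,
            "precision": self.precision, "f1": self.f1,
            "flags": list(self.flags),
            "per_run_accuracies": list(self.per_run_accuracies),
            "variance": self.variance,
        }


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with death encoded as 1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted labels differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, recall, precision, F1 from a confusion matrix.

    A ratio with zero denominator is reported as 0 and named in ``flags``
    (e.g. precision when nothing was predicted dead).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = (cm.tp + cm.tn) / cm.total
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    if precision + recall == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(acc, recall, precision, f1, flags)


def run_variance(accuracies: Sequence[float]) -> float:
    """Population variance ``(1/n) sum (mean - x_i)^2`` of per-run accuracies."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("need at least one run")
    return float(np.mean((acc.mean() - acc) ** 2))


def split_8_2(data: FusedDataset, seed: int) -> tuple[FusedDataset, FusedDataset]:
    """Stratified 80/20 train/test partition, reproducible from the seed."""
    if data.n_samples < 5:
        raise ValueError("need at least 5 samples for an 8:2 split")
    idx = np.arange(data.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=0.2, stratify=data.labels, random_state=int(seed))
    return data.subset(np.sort(train_idx)), data.subset(np.sort(test_idx))


def five_fold(train: FusedDataset, seed: int
              ) -> list[tuple[FusedDataset, FusedDataset]]:
    """Five stratified (fit, validation) splits covering the training set."""
    if train.n_samples < 5:
        raise ValueError("need at least 5 samples for five folds")
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(seed))
    return [(train.subset(fit_idx), train.subset(val_idx))
            for fit_idx, val_idx in skf.split(train.values, train.labels)]


def repeated_experiment(
    run_fn: Callable[[int], tuple[ConfusionMatrix, dict]],
    seeds: Iterable[int],
) -> tuple[MetricsReport, list[dict]]:
    """Run a full pipeline once per seed and aggregate its test metrics.

    ``run_fn(seed)`` must return the test-set confusion matrix of one round
    (plus an artifact dict, logged per round). Per-metric values are averaged
    across rounds and the across-run variance of accuracy is attached; the
    per-round confusion matrices in the log allow every reported number to
    be recomputed.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one round")
    rounds: list[dict] = []
    reports: list[MetricsReport] = []
    for seed in seeds:
        cm, artifacts = run_fn(int(seed))
        rep = metrics(cm)
        reports.append(rep)
        rounds.append({"seed": int(seed), "confusion": cm.as_dict(),
                       "metrics": rep.as_dict(), "artifacts": artifacts})
    accs = [r.accuracy for r in reports]
    agg = MetricsReport(
        accuracy=float(np.mean(accs)),
        recall=float(np.mean([r.recall for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        flags=sorted({f for r in reports for f in r.flags}),
        per_run_accuracies=[float(a) for a in accs],
        variance=run_variance(accs),
    )
    return agg, rounds
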