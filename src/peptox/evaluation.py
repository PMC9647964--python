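"""Classifier evaluation: confusion-matrix metrics, stratified k-fold
cross-validation, McNemar's paired test and length-interval error rates.

Metric conventions: accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN), and Matthews correlation
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  A metric
whose denominator vanishes is reported as 0 with a warning so fold
aggregation never aborts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import KFold, StratifiedKFold

from .sequence_io import SequenceRecord


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, labels, predictions) -> "ConfusionCounts":
        labels = np.asarray(labels, dtype=int)
        predictions = np.asarray(predictions, dtype=int)
        if labels.shape != predictions.shape:
            raise ValueError("labels and predictions must align")
        return cls(
            tp=int(np.sum((labels == 1) & (predictions == 1))),
            fp=int(np.sum((labels == 0) & (predictions == 1))),
            tn=int(np.sum((labels == 0) & (predictions == 0))),
            fn=int(np.sum((labels == 1) & (predictions == 0))),
        )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, F1 and MCC from raw counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero records")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricSet(
        accuracy=(tp + tn) / counts.total,
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        f1=_safe_ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        mcc=_safe_ratio(tp * tn - fp * fn, mcc_den, "mcc"),
    )


def make_folds(
    labels, k: int = 10, stratified: bool = True, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition indices into k (train, validation) splits.

    Stratification keeps the class ratio of every fold within one record
    of the global ratio.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} records")
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train_idx, val_idx)
        for train_idx, val_idx in splitter.split(np.zeros(n), labels)
    ]


@dataclass
class CrossValidationResult:
    fold_metrics: list[MetricSet]
    pooled: MetricSet
    pooled_counts: ConfusionCounts
    fold_sizes: list[int] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.fold_metrics]
        df = pd.DataFrame(rows)
        df.index = [f"fold_{i + 1}" for i in range(len(rows))]
        df.loc["pooled"] = self.pooled.as_dict()
        return df


def kfold_cross_validate(
    records: list[SequenceRecord],
    fit_predict,
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
) -> CrossValidationResult:
    """k-fold cross-validation: each fold serves as validation once.

    ``fit_predict(train_records, val_records, fold_index)`` must return
    0/1 predictions for the validation records.  Per-fold metrics and the
    pooled (prediction-concatenated) metrics are reported.
    """
    labels = np.array([r.label for r in records], dtype=int)
    folds = make_folds(labels, k=k, stratified=stratified, seed=seed)
    fold_metrics: list[MetricSet] = []
    fold_sizes: list[int] = []
    all_labels: list[np.ndarray] = []
    all_preds: list[np.ndarray] = []
    for fold_index, (train_idx, val_idx) in enumerate(folds):
        train = [records[i] for i in train_idx]
        val = [records[i] for i in val_idx]
        preds = np.asarray(fit_predict(train, val, fold_index), dtype=int)
        if preds.shape != (len(val),):
            raise ValueError("fit_predict returned misaligned predictions")
        counts = ConfusionCounts.from_predictions(labels[val_idx], preds)
        fold_metrics.append(compute_metrics(counts))
        fold_sizes.append(len(val))
        all_labels.append(labels[val_idx])
        all_preds.append(preds)
    pooled_counts = ConfusionCounts.from_predictions(
        np.concatenate(all_labels), np.concatenate(all_preds)
    )
    return CrossValidationResult(
        fold_metrics=fold_metrics,
        pooled=compute_metrics(pooled_counts),
        pooled_counts=pooled_counts,
        fold_sizes=fold_sizes,
    )


@dataclass(frozen=True)
class McNemarResult:
    b: int  # A right, B wrong
    c: int  # A wrong, B right
    statistic: float
    p_value: float
    method: str


def mcnemar_test(
    preds_a, preds_b, labels, method: str = "auto", exact_threshold: int = 25
) -> McNemarResult:
    """McNemar's paired test on the discordant predictions of two models.

    method "exact": two-sided binomial test on (b, b + c);
    "chi2": chi-square with continuity correction (|b - c| - 1)^2/(b + c);
    "chi2_uncorrected": (b - c)^2 / (b + c);
    "auto": exact when b + c < exact_threshold, else corrected chi-square.
    """
    preds_a = np.asarray(preds_a, dtype=int)
    preds_b = np.asarray(preds_b, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if not (preds_a.shape == preds_b.shape == labels.shape):
        raise ValueError("prediction and label vectors must align")
    right_a = preds_a == labels
    right_b = preds_b == labels
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    n = b + c
    if n == 0:
        warnings.warn("no discordant pairs; McNemar p-value is 1", stacklevel=2)
        return McNemarResult(b=b, c=c, statistic=0.0, p_value=1.0, method=method)
    if method == "auto":
        method = "exact" if n < exact_threshold else "chi2"
    if method == "exact":
        p = scipy.stats.binomtest(b, n, 0.5, alternative="two-sided").pvalue
        return McNemarResult(b=b, c=c, statistic=float(min(b, c)), p_value=float(p), method="exact")
    if method == "chi2":
        stat = (abs(b - c) - 1) ** 2 / n
    elif method == "chi2_uncorrected":
        stat = (b - c) ** 2 / n
    else:
        raise ValueError(f"unknown McNemar method {method!r}")
    p = float(scipy.stats.chi2.sf(stat, df=1))
    return McNemarResult(b=b, c=c, statistic=float(stat), p_value=p, method=method)


@dataclass
class LengthBinErrorTable:
    """Per-class, per-length-interval misclassification rates.

    Bins are half-open [lo, hi); the last bin is closed on the right so
    the maximum length is covered.  ``frame`` columns: class, bin_lo,
    bin_hi, n, errors, rate.
    """

    bin_edges: np.ndarray
    frame: pd.DataFrame


def length_interval_error_rates(
    records: list[SequenceRecord],
    predictions,
    bin_edges=None,
    n_bins: int = 10,
) -> LengthBinErrorTable:
    """Misclassification rate per length interval, split by true class.

    Default edges are deciles of the evaluated length distribution.
    """
    predictions = np.asarray(predictions, dtype=int)
    if len(predictions) != len(records):
        raise ValueError("every record needs a prediction")
    lengths = np.array([len(r) for r in records])
    labels = np.array([r.label for r in records], dtype=int)
    wrong = predictions != labels
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(lengths, qs))
        if len(bin_edges) < 2:
            bin_edges = np.array([lengths.min(), lengths.max() + 1])
    bin_edges = np.asarray(bin_edges, dtype=float)
    below = lengths < bin_edges[0]
    above = lengths > bin_edges[-1]
    if below.any() or above.any():
        warnings.warn(
            f"{int(below.sum() + above.sum())} record(s) outside the bin range; "
            "assigned to overflow bins",
            stacklevel=2,
        )
    # np.digitize with right-closed last bin
    bin_of = np.digitize(lengths, bin_edges, right=False) - 1
    bin_of[lengths == bin_edges[-1]] = len(bin_edges) - 2
    rows = []
    class_names = {1: "toxic", 0: "nontoxic"}
    for cls in (1, 0):
        in_cls = labels == cls
        for bi in range(-1, len(bin_edges)):
            if 0 <= bi <= len(bin_edges) - 2:
                lo, hi = bin_edges[bi], bin_edges[bi + 1]
                in_bin = in_cls & (bin_of == bi)
            elif bi == -1:  # underflow
                lo, hi = -np.inf, bin_edges[0]
                in_bin = in_cls & below
                if not in_bin.any():
                    continue
            else:  # overflow
                lo, hi = bin_edges[-1], np.inf
                in_bin = in_cls & above
                if not in_bin.any():
                    continue
            n = int(in_bin.sum())
            errors = int(wrong[in_bin].sum())
            rows.append(
                {
                    "class": class_names[cls],
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "n": n,
                    "errors": errors,
                    "rate": errors / n if n else 0.0,
                }
            )
    return LengthBinErrorTable(bin_edges=bin_edges, frame=pd.DataFrame(rows))
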