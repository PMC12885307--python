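"""Metrics, imbalance-ratio bookkeeping, splits, CV and the IR sweep.

Malignant is the positive class throughout (the clinically standard
choice): TP counts correctly recognized malignant samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, train_test_split

from .model import IsccadClassifier
from .schema_io import BENIGN, MALIGNANT, SampleTable
from .synthetic_data import imbalanced_subset

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_from_labels",
    "compute_metrics",
    "imbalance_ratio",
    "holdout_split",
    "cross_validate",
    "ir_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with malignant as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos, neg = MALIGNANT, BENIGN
    return ConfusionCounts(
        tp=int(((y_true == pos) & (y_pred == pos)).sum()),
        tn=int(((y_true == neg) & (y_pred == neg)).sum()),
        fp=int(((y_true == neg) & (y_pred == pos)).sum()),
        fn=int(((y_true == pos) & (y_pred == neg)).sum()),
    )


def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and F1 from confusion counts.

    Degenerate denominators (no predicted or no true positives) yield 0
    with a warning rather than NaN.
    """
    if cc.total == 0:
        raise ValueError("empty evaluation set")
    accuracy = (cc.tp + cc.tn) / cc.total
    if cc.tp + cc.fp == 0:
        logger.warning("precision undefined (no positive predictions); using 0")
        precision = 0.0
    else:
        precision = cc.tp / (cc.tp + cc.fp)
    if cc.tp + cc.fn == 0:
        logger.warning("recall undefined (no positive samples); using 0")
        recall = 0.0
    else:
        recall = cc.tp / (cc.tp + cc.fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def imbalance_ratio(n_majority: int, n_minority: int) -> float:
    """(Nmax - Nmin) / Nmin; 0 means balanced classes."""
    if n_minority <= 0:
        raise ValueError("minority class must be non-empty")
    if n_majority < n_minority:
        raise ValueError("majority count smaller than minority count")
    return (n_majority - n_minority) / n_minority


def holdout_split(
    table: SampleTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[SampleTable, SampleTable]:
    """Stratified random train/test split preserving the class mix."""
    if table.n_benign == 0 or table.n_malignant == 0:
        raise ValueError("both classes must be present for a stratified split")
    idx = np.arange(table.n)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        stratify=table.labels,
    )
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


def _default_estimator(seed: int) -> IsccadClassifier:
    return IsccadClassifier(random_state=seed)


def cross_validate(
    table: SampleTable,
    folds: int = 10,
    estimator: IsccadClassifier | None = None,
    seed: int = 0,
) -> list[MetricSet]:
    """Stratified k-fold CV re-running the full pipeline per training fold.

    Oversampling happens inside ``fit`` on the training part only, so
    synthetic rows never derive from test-fold samples.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    est = estimator if estimator is not None else _default_estimator(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out: list[MetricSet] = []
    for f, (tr, te) in enumerate(skf.split(table.values, table.labels)):
        y_tr = table.labels[tr]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"fold {f}: training part contains a single class")
        clf = clone(est)
        clf.fit(table.values[tr], y_tr)
        y_pred = clf.predict(table.values[te])
        out.append(compute_metrics(confusion_from_labels(table.labels[te], y_pred)))
    return out


def ir_sweep(
    table: SampleTable,
    ir_grid,
    estimator: IsccadClassifier | None = None,
    seed: int = 0,
    test_table: SampleTable | None = None,
    train_fraction: float = 0.8,
) -> list[dict]:
    """Retrain at several imbalance ratios against one fixed test set.

    When ``test_table`` is given, all of ``table`` is the training pool;
    otherwise a stratified hold-out split of ``table`` fixes the test set
    first.  For each grid value the training majority class is down-sampled
    (minority untouched), the pipeline retrained, and metrics computed on
    the unchanged test set.
    """
    if test_table is None:
        train, test = holdout_split(table, train_fraction, seed)
    else:
        train, test = table, test_table
    est = estimator if estimator is not None else _default_estimator(seed)
    current_ir = imbalance_ratio(
        max(train.n_benign, train.n_malignant),
        min(train.n_benign, train.n_malignant),
    )
    bad = [ir for ir in ir_grid if ir > current_ir + 1e-12]
    if bad:
        raise ValueError(f"unachievable imbalance ratios {bad} (train IR {current_ir:.4f})")

    rows: list[dict] = []
    for ir in ir_grid:
        sub = imbalanced_subset(train, ir, seed=seed)
        clf = clone(est)
        clf.fit(sub.values, sub.labels)
        y_pred = clf.predict(test.values)
        ms = compute_metrics(confusion_from_labels(test.labels, y_pred))
        n_maj = max(sub.n_benign, sub.n_malignant)
        n_min = min(sub.n_benign, sub.n_malignant)
        rows.append(
            {
                "target_ir": float(ir),
                "n_majority_train": n_maj,
                "n_minority_train": n_min,
                "realized_ir": imbalance_ratio(n_maj, n_min),
                "metrics": ms,
            }
        )
    return rows
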