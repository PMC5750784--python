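"""Cross-validation protocol, accuracy metrics and model comparison.

Ten-fold cross-validation partitions the n gait segments into per-fold
disjoint test / validation / training sets of sizes

    test       = floor(n / 10)
    validation = floor((n - n/10) / 5)
    training   = floor(4 (n - n/10) / 5)

(n/10 taken as a real number inside the floors).  These floors need not sum
to n; any leftover segments join the training set.  Validation is used for
learning the fusion decision thresholds and for nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


def cv_fold_sizes(n: int) -> Tuple[int, int, int]:
    """(test, validation, training) sizes of one 10-CV fold."""
    test = math.floor(n / 10)
    rest = n - n / 10.0
    return test, math.floor(rest / 5.0), math.floor(4.0 * rest / 5.0)


@dataclass
class SplitSpec:
    """Per-fold disjoint (test, validation, training) index sets."""

    n: int
    folds: List[Tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __iter__(self):
        return iter(self.folds)


def make_10cv_splits(n: int, seed: int,
                     labels: Optional[Sequence[int]] = None) -> SplitSpec:
    """Seeded ten-fold splits with the fold-size arithmetic above.

    When ``labels`` are given the permutation interleaves the classes so
    every subject is represented in each test fold (without stratification a
    subject could vanish from a fold's training set).  Test sets are disjoint
    across folds; within a fold the three sets are pairwise disjoint and any
    leftover indices are assigned to training.
    """
    if n < 50:
        raise ValueError("need n >= 50 for non-degenerate ten-fold splits")
    rng = np.random.default_rng(seed)
    test_size, val_size, _ = cv_fold_sizes(n)
    if labels is None:
        perm = rng.permutation(n)
    else:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labels must have length n")
        # permute within each class, then deal classes round-robin so each
        # contiguous chunk is class-balanced
        order_within = np.zeros(n, dtype=int)
        class_rank = np.zeros(n, dtype=int)
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            order_within[idx] = np.arange(len(idx))
            class_rank[idx] = np.searchsorted(np.unique(labels), c)
        perm = np.lexsort((class_rank, order_within))
    folds = []
    all_idx = np.arange(n)
    for f in range(10):
        test = np.sort(perm[f * test_size:(f + 1) * test_size])
        rest = np.setdiff1d(all_idx, test, assume_unique=True)
        rest = rng.permutation(rest)
        val = np.sort(rest[:val_size])
        train = np.sort(rest[val_size:])
        folds.append((test, val, train))
    return SplitSpec(n=n, folds=folds)


@dataclass
class EvalReport:
    """Accuracy summaries for one or more classification systems."""

    overall: float                                  # percent correct
    per_subject: Dict[int, float] = field(default_factory=dict)
    per_fold: List[float] = field(default_factory=list)
    extras: Dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.overall <= 100.0):
            raise ValueError("accuracy must be a percentage in [0, 100]")


def evaluate_accuracy(predictions: Sequence[int], labels: Sequence[int],
                      fold_ids: Optional[Sequence[int]] = None) -> EvalReport:
    """Overall and per-subject percent-correct (plus per-fold when given)."""
    preds = np.asarray(predictions)
    labels = np.asarray(labels)
    if preds.size == 0 or preds.shape != labels.shape:
        raise ValueError("predictions and labels must be non-empty and aligned")
    correct = preds == labels
    per_subject = {int(c): float(100.0 * correct[labels == c].mean())
                   for c in np.unique(labels)}
    per_fold: List[float] = []
    if fold_ids is not None:
        fold_ids = np.asarray(fold_ids)
        per_fold = [float(100.0 * correct[fold_ids == f].mean())
                    for f in np.unique(fold_ids)]
    return EvalReport(overall=float(100.0 * correct.mean()),
                      per_subject=per_subject, per_fold=per_fold)


def relative_error_reduction(a: float, b: float) -> float:
    """Relative error reduction 100 (a - b) / (100 - b), to one decimal.

    ``a`` is the improved accuracy (percent), ``b`` the baseline.  Undefined
    for a perfect baseline.
    """
    if not (0.0 <= b < 100.0):
        raise ValueError("baseline accuracy must lie in [0, 100)")
    if a < b:
        raise ValueError("improved accuracy must be >= the baseline")
    return round(100.0 * (a - b) / (100.0 - b), 1)


def compare_models(acc_a: Sequence[float],
                   acc_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample t statistic and two-sided p-value between accuracy samples."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 accuracy samples per group")
    t, p = stats.ttest_ind(a, b)
    if np.isnan(p):  # identical zero-variance groups
        p = 1.0
        t = 0.0
    return float(t), float(p)
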