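"""Cross-validation splits, confusion-matrix accounting and metrics.

Positive class = incorrectly seated condyle throughout, so sensitivity
measures detection of seating problems.  Metrics are reported both pooled
over all validation folds (every joint is validated exactly once, so the
pooled confusion matrix covers the whole dataset) and per fold; AUC is
additionally reported as the per-fold mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class FoldSplit:
    k: int
    assignments: Dict[str, int]  # joint_id -> fold index

    def validation_ids(self, fold: int) -> list:
        return [j for j, f in self.assignments.items() if f == fold]

    def training_ids(self, fold: int) -> list:
        return [j for j, f in self.assignments.items() if f != fold]


def stratified_kfold(labels: Dict[str, str], k: int = 5, rng_seed: int = 0) -> FoldSplit:
    """Stratified k-fold assignment: seeded per-class shuffle, round-robin deal.

    Per-fold class counts differ by at most one from perfect stratification;
    with class sizes divisible by k the split is exact (e.g. 85/35 at k = 5
    gives 17 + 7 validation joints per fold).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(rng_seed)
    assignments: Dict[str, int] = {}
    by_class: Dict[str, list] = {}
    for joint_id in sorted(labels):
        by_class.setdefault(labels[joint_id], []).append(joint_id)
    for cls, members in sorted(by_class.items()):
        if len(members) < k:
            raise ValueError(
                f"class {cls!r} has {len(members)} members, fewer than k={k}"
            )
        order = rng.permutation(len(members))
        for pos, idx in enumerate(order):
            assignments[members[idx]] = pos % k
    return FoldSplit(k=k, assignments=assignments)


def confusion(y_true: Sequence[bool], y_pred: Sequence[bool]) -> ConfusionMatrix:
    """Counts with positive = incorrectly seated (True)."""
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> Dict[str, Optional[float]]:
    """The six classification metrics; undefined ratios reported as None.

    accuracy = (TP+TN)/total, precision (PPV) = TP/(TP+FP),
    NPV = TN/(TN+FN), F1 (dice) = 2TP/(2TP+FP+FN),
    sensitivity (recall) = TP/(TP+FN), specificity = TN/(TN+FP).
    """
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "precision_ppv": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "f1": _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
    }


def roc_auc(confidences: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC by the rank (Mann–Whitney) formulation with midranks for ties."""
    c = np.asarray(confidences, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if c.shape != y.shape:
        raise ValueError("confidences and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(c)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(confidences: Sequence[float], labels: Sequence[bool]):
    """(fpr, tpr) points over all distinct thresholds, for plotting/export."""
    c = np.asarray(confidences, dtype=float)
    y = np.asarray(labels, dtype=bool)
    order = np.argsort(-c, kind="stable")
    c, y = c[order], y[order]
    n_pos = y.sum()
    n_neg = y.size - n_pos
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.r_[np.nonzero(np.diff(c))[0], y.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given decimals (printed-value match)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def recover_confusion_matrix(
    sens_2dp: float, spec_2dp: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Invert printed sensitivity/specificity to the integer confusion matrix.

    Exhaustively searches TP in [0, n_pos] and TN in [0, n_neg] for counts
    whose sensitivity and specificity round (half-up, 2 dp) to the inputs;
    returns the matrix iff it is unique, else raises listing candidates.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    tps = [
        tp for tp in range(n_pos + 1)
        if round_half_up(tp / n_pos) == round_half_up(sens_2dp)
    ]
    tns = [
        tn for tn in range(n_neg + 1)
        if round_half_up(tn / n_neg) == round_half_up(spec_2dp)
    ]
    candidates = [(tp, tn) for tp in tps for tn in tns]
    if len(candidates) != 1:
        raise ValueError(
            f"confusion matrix not uniquely recoverable: {len(candidates)} "
            f"candidates {candidates[:10]}"
        )
    tp, tn = candidates[0]
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
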