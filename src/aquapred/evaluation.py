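"""Binary-classification metrics and stratified cross-validation.

Sn, Sp and Acc are reported in percent; MCC in [-1, 1] and AUROC in [0, 1]
as unit-scale reals.  AUROC uses the rank (Mann-Whitney) formulation: the
probability that a uniformly chosen positive outscores a uniformly chosen
negative, ties counted 1/2, which equals the trapezoidal area under the ROC
curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, TYPE_CHECKING

import numpy as np
from scipy.stats import rankdata
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

if TYPE_CHECKING:  # pragma: no cover
    from .classify import ClassifierSpec
    from .encoder import FeatureMatrix


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """Sn/Sp/Acc in percent, MCC in [-1,1], AUROC in [0,1] (optional)."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auroc: Optional[float] = None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Standard confusion counts with positive class = 1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy (percent) and MCC from counts.

    Zero-denominator convention: any undefined ratio (no positives, no
    negatives, or a zero MCC denominator factor) evaluates to 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    sn = _safe_div(c.tp, c.tp + c.fn) * 100.0
    sp = _safe_div(c.tn, c.tn + c.fp) * 100.0
    acc = (c.tp + c.tn) / c.total * 100.0
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def auroc(y_true, scores) -> float:
    """Rank-based AUROC; ties counted 1/2 (Mann-Whitney U / (n+ * n-))."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)  # mid-ranks for ties
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(y_true, scores) -> np.ndarray:
    """ROC points as an (n, 2) array of (FPR, TPR), from (0,0) to (1,1).

    Thresholds at distinct score values; the trapezoidal area under the
    returned polyline equals :func:`auroc` on the same inputs.
    """
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _skm.roc_curve(y_true, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


@dataclass
class CVReport:
    """Per-fold and aggregate metrics for one classifier on one dataset."""

    per_fold: list[MetricSet]
    mean: MetricSet
    pooled: MetricSet
    fold_assignments: np.ndarray
    seed: int
    k: int
    classifier: str = ""

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "k": self.k,
            "seed": self.seed,
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": self.mean.as_dict(),
            "pooled": self.pooled.as_dict(),
        }

    def tsv_row(self, label: str = "", which: str = "mean") -> str:
        """One row in the Sn/Sp/Acc/MCC/AUROC layout."""
        m = self.mean if which == "mean" else self.pooled
        return (
            f"{label}\t{m.sn:.3f}\t{m.sp:.3f}\t{m.acc:.3f}\t{m.mcc:.4f}\t{m.auroc:.4f}"
        )


TSV_HEADER = "dataset\tSn\tSp\tAcc\tMCC\tAUROC"


def _mean_metrics(folds: list[MetricSet]) -> MetricSet:
    return MetricSet(
        sn=float(np.mean([m.sn for m in folds])),
        sp=float(np.mean([m.sp for m in folds])),
        acc=float(np.mean([m.acc for m in folds])),
        mcc=float(np.mean([m.mcc for m in folds])),
        auroc=float(np.mean([m.auroc for m in folds])),
    )


def stratified_kfold(
    matrix: "FeatureMatrix",
    spec: "ClassifierSpec",
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of one classifier spec.

    Each fold is held out once; the classifier is trained on the remaining
    folds and scored on the held-out samples (AUROC from the continuous
    positive-class score).  ``mean`` is the unweighted average over folds;
    ``pooled`` recomputes every metric over the concatenated out-of-fold
    predictions.  Fully reproducible given ``seed`` and ``spec.seed``.
    """
    from .classify import predict, train  # deferred: avoid import cycle

    y = np.asarray(matrix.labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in (0, 1):
        n_cls = int(np.sum(y == cls))
        if n_cls < k:
            raise ValueError(
                f"class {cls} has {n_cls} samples but k={k}; "
                "reduce k or provide more samples of that class"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    per_fold: list[MetricSet] = []
    oof_pred = np.empty(len(y), dtype=int)
    oof_score = np.empty(len(y), dtype=float)
    from .encoder import FeatureMatrix as FM

    for fold, (tr, te) in enumerate(skf.split(matrix.X, y)):
        assignments[te] = fold
        sub_train = FM(
            matrix.X[tr], matrix.feature_names, y[tr], [matrix.ids[i] for i in tr]
        )
        sub_test = FM(
            matrix.X[te], matrix.feature_names, y[te], [matrix.ids[i] for i in te]
        )
        model = train(sub_train, spec)
        labels, scores = predict(model, sub_test)
        oof_pred[te] = labels
        oof_score[te] = scores
        m = metrics(confusion_counts(y[te], labels))
        m.auroc = auroc(y[te], scores)
        per_fold.append(m)
    pooled = metrics(confusion_counts(y, oof_pred))
    pooled.auroc = auroc(y, oof_score)
    return CVReport(
        per_fold=per_fold,
        mean=_mean_metrics(per_fold),
        pooled=pooled,
        fold_assignments=assignments,
        seed=seed,
        k=k,
        classifier=spec.family,
    )
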