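"""Confusion-matrix metrics, rank-based AUC and k-fold cross-validation.

Seven metrics summarise a binary PPI predictor: accuracy (ACC), precision
(PE), recall/sensitivity (RE), specificity (SPE), Matthews correlation
coefficient (MCC), F1 and the area under the ROC curve (AUC).  Metrics with
a zero denominator are reported as missing (``None``), never silently as 0.

Cross-validation is stratified by class so every fold keeps the dataset's
class balance, and the fold assignment is a pure function of the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .model import MLPConfig, build, predict, train

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "confusion",
    "metrics",
    "roc_auc",
    "roc_curve_table",
    "evaluate",
    "cross_validate",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "PE", "RE", "SPE", "MCC", "F1", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies at a fixed decision threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The seven evaluation metrics; undefined values are ``None``."""

    ACC: float | None = None
    PE: float | None = None
    RE: float | None = None
    SPE: float | None = None
    MCC: float | None = None
    F1: float | None = None
    AUC: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Tally the confusion matrix; probability >= threshold predicts positive."""
    y = np.asarray(labels).ravel()
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    if y.size == 0:
        raise ValueError("cannot tally an empty prediction set")
    if y.size != p.size:
        raise ValueError("labels and probabilities differ in length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from a confusion table (AUC left unset).

    ACC = (TP+TN)/all, PE = TP/(TP+FP), RE = TP/(TP+FN), SPE = TN/(TN+FP),
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) and
    F1 = 2TP/(2TP+FP+FN); a metric whose denominator is zero is undefined.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricsReport(
        ACC=_safe_div(tp + tn, c.total),
        PE=_safe_div(tp, tp + fp),
        RE=_safe_div(tp, tp + fn),
        SPE=_safe_div(tn, tn + fp),
        MCC=(tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None,
        F1=_safe_div(2 * tp, 2 * tp + fp + fn),
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count one half.

    Equals the probability that a random positive outscores a random
    negative, and the trapezoidal area under the full-threshold ROC curve.
    """
    y = np.asarray(labels).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined when only one class is present")
    ranks = rankdata(s)  # average ranks handle ties
    rank_sum = float(ranks[y == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve_table(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR, threshold) rows of the full-threshold-sweep ROC curve."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr])


def evaluate(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """All seven metrics for one set of predictions."""
    report = metrics(confusion(labels, probabilities, threshold))
    y = np.asarray(labels).ravel()
    auc = None
    if 0 < np.sum(y == 1) < y.size:
        auc = roc_auc(labels, probabilities)
    return MetricsReport(**{**report.as_dict(), "AUC": auc})


@dataclass
class CVResult:
    """Per-fold metric reports plus mean and sample standard deviation."""

    folds: list[MetricsReport]
    mean: MetricsReport
    sd: MetricsReport
    fold_assignment: np.ndarray  # fold index per input row
    oof_probabilities: np.ndarray | None = None  # out-of-fold score per row

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean.as_dict(),
            "sd": self.sd.as_dict(),
        }


def _aggregate(folds: list[MetricsReport]) -> tuple[MetricsReport, MetricsReport]:
    means: dict[str, float | None] = {}
    sds: dict[str, float | None] = {}
    for name in METRIC_NAMES:
        vals = [getattr(f, name) for f in folds if getattr(f, name) is not None]
        if not vals:
            means[name] = None
            sds[name] = None
            continue
        means[name] = float(np.mean(vals))
        sds[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return MetricsReport(**means), MetricsReport(**sds)


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    config: MLPConfig | None = None,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold cross-validation of the feed-forward classifier.

    Rows are shuffled once under ``seed`` and split into k near-equal folds
    preserving class balance; for each fold a fresh model is trained on the
    other k-1 folds and scored on the held-out rows.  Aggregates are the
    mean and sample (n-1) standard deviation over folds.
    """
    X = np.asarray(features)
    y = np.asarray(labels).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")
    if config is None:
        config = MLPConfig(input_dim=X.shape[1], seed=seed)

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.full(y.size, -1, dtype=np.int64)
    oof = np.full(y.size, np.nan)
    reports: list[MetricsReport] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        fold_assignment[test_idx] = fold
        model = build(config)
        train(model, X[train_idx], y[train_idx])
        probs = predict(model, X[test_idx])
        oof[test_idx] = probs
        report = metrics(confusion(y[test_idx], probs, threshold))
        y_test = y[test_idx]
        if 0 < np.sum(y_test == 1) < y_test.size:
            auc = roc_auc(y_test, probs)
        else:
            auc = None
            logger.warning("fold %d holds a single class; AUC undefined", fold)
        reports.append(MetricsReport(**{**report.as_dict(), "AUC": auc}))
    mean, sd = _aggregate(reports)
    return CVResult(
        folds=reports,
        mean=mean,
        sd=sd,
        fold_assignment=fold_assignment,
        oof_probabilities=oof,
    )
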