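"""Binary-classification metrics, ROC/AUC, and the cross-validation driver.

Two quantities both called "AUC" in this literature are kept strictly
apart here:

* ``roc_auc`` — the rank-based area under the ROC curve (equivalently
  the Mann-Whitney probability that a random positive outscores a random
  negative, ties counted half).  This is the AUC used in reports.
* ``balanced_auc`` — (Sn + Sp) / 2, i.e. balanced accuracy at a fixed
  threshold; some papers print this formula under the AUC name, so it is
  exposed under its own name and never conflated with the ROC area.

Undefined metrics (zero denominators) surface as NaN sentinels with a
warning, never as silent zeros.  A probability exactly at the decision
threshold counts as a positive call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts of a binary cross-tabulation."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v}")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricReport:
    """The standard metric suite; NaN marks an undefined (0/0) entry."""

    ACC: float
    Sn: float
    Sp: float
    Precision: float
    F1: float
    MCC: float
    roc_auc: float = math.nan
    balanced_auc: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    """Cross-tabulate labels against thresholded probabilities.

    Prediction is positive when probability >= threshold (ties count
    positive).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = p >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return math.nan
    return num / den


def metrics(cc: ConfusionCounts) -> MetricReport:
    """ACC, Sn, Sp, Precision, F1 and MCC from confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN));
    F1 = 2TP / (2TP + FP + FN).
    """
    tp, tn, fp, fn = cc.TP, cc.TN, cc.FP, cc.FN
    acc = (tp + tn) / cc.n
    sn = _safe_div(tp, tp + fn, "Sn")
    sp = _safe_div(tn, tn + fp, "Sp")
    precision = _safe_div(tp, tp + fp, "Precision")
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "F1")
    mcc_den = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    bal = (sn + sp) / 2 if not (math.isnan(sn) or math.isnan(sp)) else math.nan
    return MetricReport(
        ACC=acc, Sn=sn, Sp=sp, Precision=precision, F1=f1, MCC=mcc, balanced_auc=bal
    )


def balanced_auc(cc: ConfusionCounts) -> float:
    """(Sn + Sp) / 2 — balanced accuracy at the fixed threshold."""
    sn = _safe_div(cc.TP, cc.TP + cc.FN, "Sn")
    sp = _safe_div(cc.TN, cc.TN + cc.FP, "Sp")
    return (sn + sp) / 2


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Rank-based ROC AUC plus the curve's (fpr, tpr, thresholds) points."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s)
    return auc, fpr, tpr, thresholds


def evaluate_predictions(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> MetricReport:
    """Full report: threshold metrics plus rank-based ROC AUC."""
    cc = confusion(labels, probabilities, threshold)
    rep = metrics(cc)
    y = np.asarray(labels, dtype=int)
    auc = math.nan
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))
    return MetricReport(**{**rep.as_dict(), "roc_auc": auc})


def cross_validate(
    fm,
    model_builder: Callable[[int], object],
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Stratified k-fold evaluation of a model builder on a feature matrix.

    ``model_builder(seed)`` returns an unfitted estimator with
    ``fit``/``predict_proba``.  Returns per-fold reports, the pooled
    out-of-fold report, the fold assignment, and the pooled out-of-fold
    probabilities.
    """
    y = fm.y
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes")
    if fm.n < folds:
        raise ValueError(f"n={fm.n} < folds={folds}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.full(fm.n, np.nan)
    fold_of_row = np.full(fm.n, -1, dtype=int)
    per_fold = []
    for f, (train_idx, test_idx) in enumerate(skf.split(fm.X, y)):
        model = model_builder(seed)
        model.fit(fm.X[train_idx], y[train_idx])
        proba = model.predict_proba(fm.X[test_idx])
        pos_col = list(model.classes_).index(1)
        pooled[test_idx] = proba[:, pos_col]
        fold_of_row[test_idx] = f
        if len(np.unique(y[test_idx])) == 2:
            per_fold.append(evaluate_predictions(y[test_idx], pooled[test_idx], threshold))
        else:
            per_fold.append(metrics(confusion(y[test_idx], pooled[test_idx], threshold)))
    report = evaluate_predictions(y, pooled, threshold)
    return {
        "per_fold": per_fold,
        "pooled": report,
        "fold_of_row": fold_of_row,
        "oof_probabilities": pooled,
        "seed": seed,
        "folds": folds,
    }


def write_metrics_table(reports: dict[str, MetricReport], path) -> None:
    """Tab-separated metrics table, one row per model/dataset label."""
    keys = [f.name for f in fields(MetricReport)]
    with open(path, "w") as fh:
        fh.write("model\t" + "\t".join(keys) + "\n")
        for label, rep in reports.items():
            fh.write(label + "\t" + "\t".join(f"{getattr(rep, k):.4f}" for k in keys) + "\n")


def write_roc_points(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray, path) -> None:
    """ROC curve points as tab-separated text for external plotting."""
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\tthreshold\n")
        for a, b, t in zip(fpr, tpr, thresholds):
            fh.write(f"{a:.6f}\t{b:.6f}\t{t:.6g}\n")
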