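"""Binary-classification metrics and the stratified cross-validation harness.

Sulphenylated cysteines are the positive class. AUC uses the
Mann-Whitney rank formulation with tie correction (ties count half),
which equals the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the derived performance measures."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(labels, predicted) -> Metrics:
    """Sensitivity, specificity, accuracy and MCC from 0/1 label vectors.

    MCC is defined as 0 when its denominator vanishes (degenerate
    confusion table); the convention is logged.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(predicted).astype(int)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / y.size
    denom = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    if denom == 0:
        logger.debug("MCC denominator is 0; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return Metrics(tp, tn, fp, fn, sens, spec, acc, mcc)


def roc_auc(labels, scores) -> float:
    """Probability that a random positive outranks a random negative.

    Rank-based (Mann-Whitney) with midranks for ties, identical to the
    trapezoidal ROC area.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class CVSpec:
    """Stratified k-fold specification (10 folds by default)."""

    n_folds: int = 10
    seed: int = 0

    def splitter(self) -> StratifiedKFold:
        return StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.seed
        )

    def check(self, labels) -> None:
        y = np.asarray(labels).astype(int)
        smallest = min(int(np.sum(y == 1)), int(np.sum(y == 0)))
        if smallest < self.n_folds:
            raise ValueError(
                f"{self.n_folds}-fold CV impossible: smallest class has "
                f"{smallest} samples; use n_folds <= {smallest}"
            )


def with_auc(metrics: Metrics, auc: float) -> Metrics:
    return Metrics(**{**metrics.as_dict(), "auc": auc})


def cross_validate(
    fit_score, X, labels, cv: CVSpec, threshold: float = 0.5
) -> dict:
    """Generic out-of-fold evaluation harness.

    ``fit_score(X_train, y_train, X_test) -> scores`` returns
    positive-class scores for the test rows. Returns per-fold metrics,
    pooled metrics on the concatenated out-of-fold scores (the headline
    numbers), and the out-of-fold score vector itself.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    cv.check(y)
    oof = np.full(y.shape, np.nan)
    fold_metrics: list[Metrics] = []
    for train_idx, test_idx in cv.splitter().split(X, y):
        scores = np.asarray(fit_score(X[train_idx], y[train_idx], X[test_idx]))
        oof[test_idx] = scores
        m = confusion_metrics(y[test_idx], (scores >= threshold).astype(int))
        try:
            m = with_auc(m, roc_auc(y[test_idx], scores))
        except ValueError:
            pass  # degenerate fold: single class
        fold_metrics.append(m)
    pooled = with_auc(
        confusion_metrics(y, (oof >= threshold).astype(int)), roc_auc(y, oof)
    )
    return {"folds": fold_metrics, "pooled": pooled, "oof_scores": oof}


def summarize_folds(fold_metrics: list[Metrics]) -> dict[str, tuple[float, float]]:
    """Per-fold mean and standard deviation of each measure."""
    out = {}
    for key in ("sensitivity", "specificity", "accuracy", "mcc", "auc"):
        vals = [getattr(m, key) for m in fold_metrics if getattr(m, key) is not None]
        if vals:
            out[key] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
    return out
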