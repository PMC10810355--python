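"""Binary-classification evaluation: ROC/AUC, threshold metrics, fold tests.

The diagnosis task is AD (positive) vs NC (negative).  At a decision
threshold ``t`` a record is called AD iff its predicted AD-probability is
``>= t`` (inclusive; the conventional default threshold is 0.5), and

    accuracy    = (TN + TP) / (TN + TP + FN + FP)
    sensitivity =  TP / (TP + FN)
    specificity =  TN / (TN + FP)

AUC is the trapezoidal area under the ROC curve, which equals the
Mann-Whitney probability that a random positive outscores a random negative
(ties counted 1/2).  :func:`mann_whitney_auc` provides the all-pairs form as
an independent cross-check of the trapezoidal implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ScoredSet",
    "EvalReport",
    "SingleClassError",
    "roc_curve",
    "auc",
    "mann_whitney_auc",
    "confusion_metrics",
    "evaluate",
    "operating_point",
    "compare_across_folds",
    "reports_frame",
]


class SingleClassError(ValueError):
    """Raised when an operation needs both classes but only one is present."""


@dataclass(frozen=True)
class ScoredSet:
    """Per-record ground truth and predicted AD-probability."""

    ids: tuple[str, ...]
    y_true: np.ndarray  # 1 = AD, 0 = NC
    scores: np.ndarray  # P(AD)

    def __post_init__(self) -> None:
        y = np.asarray(self.y_true, dtype=int)
        s = np.asarray(self.scores, dtype=float)
        if y.shape != s.shape or y.ndim != 1 or len(self.ids) != y.size:
            raise ValueError("ids, y_true and scores must be 1-D and aligned")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if (s < 0).any() or (s > 1).any():
            raise ValueError("scores must be probabilities in [0, 1]")
        object.__setattr__(self, "y_true", y)
        object.__setattr__(self, "scores", s)

    @property
    def has_both_classes(self) -> bool:
        return 0 < self.y_true.sum() < self.y_true.size


@dataclass(frozen=True)
class EvalReport:
    """Threshold metrics plus (optionally) the ROC curve and its AUC.

    ``sensitivity``/``specificity`` are ``None`` when undefined (no
    positives / no negatives in the evaluated set) rather than 0.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None = None
    roc: tuple[tuple[float, float], ...] | None = None
    warning: str | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }
        if self.roc is not None:
            d["roc"] = [list(p) for p in self.roc]
        if self.warning:
            d["warning"] = self.warning
        return d


def _require_both(scored: ScoredSet) -> None:
    if not scored.has_both_classes:
        raise SingleClassError("ROC analysis needs both classes present")


def roc_curve(scored: ScoredSet) -> tuple[tuple[float, float], ...]:
    """Ordered (FPR, TPR) points, one per distinct score threshold.

    Monotone non-decreasing in both coordinates, pinned at (0, 0) and
    (1, 1).
    """
    _require_both(scored)
    fpr, tpr, _ = _sk_roc_curve(scored.y_true, scored.scores, drop_intermediate=False)
    return tuple(zip(map(float, fpr), map(float, tpr)))


def auc(scored: ScoredSet) -> float:
    """Trapezoidal area under the ROC curve."""
    points = roc_curve(scored)
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


def mann_whitney_auc(scored: ScoredSet) -> float:
    """All-pairs AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Brute-force over every positive-negative pair; serves as an independent
    cross-check of :func:`auc`.
    """
    _require_both(scored)
    pos = scored.scores[scored.y_true == 1]
    neg = scored.scores[scored.y_true == 0]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def confusion_metrics(scored: ScoredSet, threshold: float = 0.5) -> EvalReport:
    """Confusion counts and accuracy/sensitivity/specificity at a threshold.

    Prediction rule: AD iff probability >= threshold.
    """
    pred = scored.scores >= threshold
    y = scored.y_true.astype(bool)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    n_pos, n_neg = tp + fn, tn + fp
    return EvalReport(
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tn + tp) / (tn + tp + fn + fp),
        sensitivity=tp / n_pos if n_pos else None,
        specificity=tn / n_neg if n_neg else None,
    )


def evaluate(scored: ScoredSet, threshold: float = 0.5) -> EvalReport:
    """Full report: confusion metrics at ``threshold`` plus ROC and AUC."""
    base = confusion_metrics(scored, threshold)
    points = roc_curve(scored)
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return EvalReport(
        **{**base.__dict__, "auc": float(np.trapezoid(tpr, fpr)), "roc": points}
    )


def operating_point(
    scored: ScoredSet, target_sensitivity: float
) -> tuple[float, EvalReport]:
    """Largest threshold whose sensitivity meets a target.

    Screening use favours sensitivity: sweeping the threshold down from the
    top trades specificity for sensitivity.  Returns the highest threshold
    (most specific operating point) with sensitivity >= target, and the
    report there.  If the target is unreachable the minimal threshold is
    returned with a warning flag on the report.
    """
    if not 0 < target_sensitivity <= 1:
        raise ValueError("target sensitivity must lie in (0, 1]")
    _require_both(scored)
    thresholds = np.unique(scored.scores)[::-1]  # descending
    for t in thresholds:
        rep = confusion_metrics(scored, float(t))
        if rep.sensitivity is not None and rep.sensitivity >= target_sensitivity:
            rep = evaluate(scored, float(t))
            return float(t), rep
    t = float(thresholds[-1])
    rep = evaluate(scored, t)
    return t, EvalReport(
        **{**rep.__dict__, "warning": "target sensitivity unreachable"}
    )


def compare_across_folds(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value on per-fold AUCs.

    Folds are paired by index, so both runs must use the same split.  The
    degenerate cases are handled explicitly: identical fold values give
    p = 1, a constant non-zero difference (zero variance of differences)
    gives p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length paired fold AUCs")
    if a.size < 2:
        raise ValueError("paired test needs at least 2 folds")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0 if np.allclose(d, 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def reports_frame(reports: dict[str, EvalReport]):
    """Summary table of holdout-style reports, one row per method.

    Column order follows the conventional presentation: accuracy,
    sensitivity, specificity, then AUC, all in percent.
    """
    import pandas as pd

    rows = []
    for name, r in reports.items():
        rows.append({
            "method": name,
            "accuracy_pct": round(100 * r.accuracy, 2),
            "sensitivity_pct": (
                None if r.sensitivity is None else round(100 * r.sensitivity, 2)
            ),
            "specificity_pct": (
                None if r.specificity is None else round(100 * r.specificity, 2)
            ),
            "auc_pct": None if r.auc is None else round(100 * r.auc, 2),
        })
    return pd.DataFrame(
        rows,
        columns=["method", "accuracy_pct", "sensitivity_pct",
                 "specificity_pct", "auc_pct"],
    )
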