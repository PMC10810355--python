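"""Diagnosis pipeline: feature assembly, model training, CV protocols.

The classifier input for one eye is the vector of selected FAZ shape
descriptors followed by the two clinical correction covariates, age and
sex.  The reference model is a light gradient-boosting machine (LGBM);
XGBoost and random forest are available as alternative families.  All
protocols of the evaluation design are implemented here:

* stratified fivefold cross-validation with per-fold AUC (mean +/- SD),
* the incremental feature-ablation ladder
  area -> +compactness -> +eccentricity -> +roundness -> +solidity,
* isolated single-feature runs (each descriptor alone, plus covariates),
* a strict train/holdout evaluation with an identifier-level leakage audit.

Hyperparameters are library defaults with fixed seeds; no tuning protocol
is applied, which keeps the model-family and feature-subset comparisons
honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .geometry import FEATURE_NAMES
from .metrics import EvalReport, ScoredSet, evaluate
from .synthetic import SubjectRecord

__all__ = [
    "MODEL_FAMILIES",
    "ABLATION_LADDER",
    "LeakageError",
    "FoldSplit",
    "TrainedModel",
    "CVResult",
    "assemble_vector",
    "design_matrix",
    "stratified_kfold",
    "train",
    "predict_proba",
    "score_records",
    "run_cv",
    "ablation_ladder",
    "single_feature_runs",
    "holdout_evaluate",
]

MODEL_FAMILIES = ("lgbm", "xgboost", "random_forest")

#: nested subsets of the incremental ablation, in evaluation order
ABLATION_LADDER: tuple[tuple[str, ...], ...] = (
    ("area",),
    ("area", "compactness"),
    ("area", "compactness", "eccentricity"),
    ("area", "compactness", "eccentricity", "roundness"),
    ("area", "compactness", "eccentricity", "roundness", "solidity"),
)

COVARIATES = ("age", "sex")


class LeakageError(RuntimeError):
    """Raised when train and evaluation sets share record identifiers."""


def _validate_subset(subset: Sequence[str]) -> tuple[str, ...]:
    subset = tuple(subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    if len(set(subset)) != len(subset):
        raise ValueError("feature subset contains duplicates")
    unknown = [f for f in subset if f not in FEATURE_NAMES]
    if unknown:
        raise KeyError(f"unknown feature(s): {', '.join(unknown)}")
    return subset


def assemble_vector(record: SubjectRecord, subset: Sequence[str]) -> np.ndarray:
    """Numeric input vector: selected shape features, then age, then sex."""
    subset = _validate_subset(subset)
    feats = record.features.as_dict()
    return np.array([feats[f] for f in subset] + [record.age, float(record.sex)])


def design_matrix(
    records: Sequence[SubjectRecord], subset: Sequence[str]
) -> tuple["pd.DataFrame", np.ndarray, list[str]]:
    """Stack records into (X, y, column_names); y is 1 for AD."""
    import pandas as pd

    subset = _validate_subset(subset)
    names = list(subset) + list(COVARIATES)
    X = pd.DataFrame(
        np.stack([assemble_vector(r, subset) for r in records]), columns=names
    )
    y = np.array([1 if r.label == "AD" else 0 for r in records])
    return X, y, names


@dataclass(frozen=True)
class FoldSplit:
    """k disjoint, label-stratified partitions of record indices."""

    folds: tuple[tuple[int, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_test(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.array(self.folds[i])
        train = np.array(
            [j for f in range(self.k) if f != i for j in self.folds[f]]
        )
        return train, test


def stratified_kfold(
    records: Sequence[SubjectRecord], k: int, seed: int
) -> FoldSplit:
    """Deterministic label-stratified k-fold partition.

    Fold sizes differ by at most one and each fold keeps the class mix of
    the whole cohort to within one record per class.
    """
    y = np.array([1 if r.label == "AD" else 0 for r in records])
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(
                f"class {'AD' if cls else 'NC'} has fewer than k={k} records"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(
        tuple(int(i) for i in test) for _, test in skf.split(np.zeros(len(y)), y)
    )
    return FoldSplit(folds=folds, seed=seed)


@dataclass
class TrainedModel:
    """Fitted binary classifier with its training provenance."""

    estimator: object
    subset: tuple[str, ...]
    family: str
    seed: int
    train_ids: frozenset[str]

    def predict_proba(self, records: Sequence[SubjectRecord]) -> np.ndarray:
        X, _, _ = design_matrix(records, self.subset)
        return np.clip(self.estimator.predict_proba(X)[:, 1], 0.0, 1.0)


def _make_estimator(family: str, seed: int):
    if family == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    if family == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss")
    if family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, n_jobs=1)
    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


def train(
    records: Sequence[SubjectRecord],
    subset: Sequence[str],
    family: str = "lgbm",
    seed: int = 0,
) -> TrainedModel:
    """Fit one classifier (positive class = AD) on the given records."""
    subset = _validate_subset(subset)
    X, y, _ = design_matrix(records, subset)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires records from both classes")
    est = _make_estimator(family, seed)
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        subset=subset,
        family=family,
        seed=seed,
        train_ids=frozenset(r.id for r in records),
    )


def predict_proba(
    model: TrainedModel, records: Sequence[SubjectRecord]
) -> np.ndarray:
    """AD probabilities for a batch of records."""
    return model.predict_proba(records)


def score_records(
    model: TrainedModel, records: Sequence[SubjectRecord]
) -> ScoredSet:
    return ScoredSet(
        ids=tuple(r.id for r in records),
        y_true=np.array([1 if r.label == "AD" else 0 for r in records]),
        scores=model.predict_proba(records),
    )


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome for one feature subset / model family."""

    subset: tuple[str, ...]
    family: str
    k: int
    seed: int
    fold_aucs: tuple[float, ...]
    fold_reports: tuple[EvalReport, ...]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))

    def to_dict(self) -> dict:
        return {
            "config": {
                "subset": list(self.subset),
                "family": self.family,
                "k": self.k,
                "seed": self.seed,
            },
            "per_fold": [round(a, 6) for a in self.fold_aucs],
            "mean": round(self.mean_auc, 6),
            "sd": round(self.sd_auc, 6),
        }


def run_cv(
    records: Sequence[SubjectRecord],
    subset: Sequence[str],
    family: str = "lgbm",
    k: int = 5,
    seed: int = 0,
    split: FoldSplit | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation; reports per-fold AUC.

    Each fold's model is trained on the other k-1 folds and scored once on
    the held-out fold.  Passing a prebuilt ``split`` lets different feature
    subsets share exactly the same folds (paired comparisons).
    """
    subset = _validate_subset(subset)
    if split is None:
        split = stratified_kfold(records, k, seed)
    aucs: list[float] = []
    reports: list[EvalReport] = []
    for i in range(split.k):
        tr_idx, te_idx = split.train_test(i)
        model = train([records[j] for j in tr_idx], subset, family, seed)
        scored = score_records(model, [records[j] for j in te_idx])
        rep = evaluate(scored, threshold=0.5)
        reports.append(rep)
        aucs.append(float(rep.auc))
    return CVResult(
        subset=subset,
        family=family,
        k=split.k,
        seed=seed,
        fold_aucs=tuple(aucs),
        fold_reports=tuple(reports),
    )


def ablation_ladder(
    records: Sequence[SubjectRecord],
    family: str = "lgbm",
    seed: int = 0,
    k: int = 5,
) -> list[CVResult]:
    """Incremental ablation over the five nested subsets, shared folds.

    Order: area alone (the single-feature baseline), then adding
    compactness, eccentricity, roundness and solidity one at a time.
    """
    split = stratified_kfold(records, k, seed)
    return [
        run_cv(records, subset, family=family, seed=seed, split=split)
        for subset in ABLATION_LADDER
    ]


def single_feature_runs(
    records: Sequence[SubjectRecord],
    family: str = "lgbm",
    seed: int = 0,
    k: int = 5,
) -> dict[str, CVResult]:
    """One CV per isolated descriptor (plus covariates), shared folds."""
    split = stratified_kfold(records, k, seed)
    return {
        name: run_cv(records, (name,), family=family, seed=seed, split=split)
        for name in FEATURE_NAMES
    }


def holdout_evaluate(
    train_records: Sequence[SubjectRecord],
    test_records: Sequence[SubjectRecord],
    subset: Sequence[str],
    family: str = "lgbm",
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Train once on the training cohort, evaluate once on the holdout.

    Identifier overlap between the two cohorts raises
    :class:`LeakageError` before any model is fitted.
    """
    shared = {r.id for r in train_records} & {r.id for r in test_records}
    if shared:
        raise LeakageError(
            f"train/holdout identifier overlap: {sorted(shared)[:5]}"
        )
    model = train(train_records, subset, family, seed)
    return evaluate(score_records(model, test_records), threshold=threshold)
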