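"""Random-forest seizure classification and repeated cross-validated scoring.

The classifier is a bagged ensemble of unpruned CART trees (bootstrap
resampling per tree, √D feature subsampling per split, majority vote;
prediction ties break toward the seizure-free class).  Performance is
reported as sensitivity, specificity, accuracy, F-measure and Matthews
correlation coefficient — each as a percentage — from confusion counts
pooled over the folds of repeated stratified k-fold cross-validation
(defaults: 10 folds × 10 repeats) and averaged over repeats.  The positive
class is the seizure (ictal) class, encoded 1; seizure-free is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = ["ForestModel", "ConfusionCounts", "EvaluationReport", "METRIC_NAMES",
           "train_forest", "predict", "compute_metrics", "cross_validate"]

METRIC_NAMES = ("SEN", "SPEC", "ACC", "F", "MCC")


@dataclass
class ForestModel:
    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    n_trees: int
    rng_seed: int


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positive class = epileptic seizure (label 1)."""
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvaluationReport:
    fold_counts: list[list[ConfusionCounts]]  # [repeat][fold]
    repeat_metrics: list[dict]                # pooled metrics per repeat
    metrics: dict                             # mean over repeats
    n_repeats: int
    n_folds: int

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "metrics": self.metrics,
            "repeat_metrics": self.repeat_metrics,
            "fold_counts": [[vars(c) for c in rep] for rep in self.fold_counts],
        }


def _as_matrix(table) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), tuple(map(str, table.columns))
    x = np.asarray(table, dtype=float)
    return x, tuple(f"f{i}" for i in range(x.shape[1]))


def train_forest(table, labels, n_trees: int = 100, rng_seed: int = 0) -> ForestModel:
    """Fit the bagged unpruned-tree ensemble.

    Each tree grows on a bootstrap resample of the rows to maximal depth
    (splits continue until leaves are pure), with √D candidate features per
    split.
    """
    x, names = _as_matrix(table)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if len(y) < 10:
        raise ValueError("need at least 10 records to train")
    est = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_depth=None,
        max_features="sqrt", bootstrap=True, random_state=rng_seed,
    )
    est.fit(x, y)
    return ForestModel(estimator=est, feature_names=names,
                       n_trees=n_trees, rng_seed=rng_seed)


def predict(model: ForestModel, rows) -> np.ndarray:
    """Majority vote over the ensemble; exact vote ties go to the
    seizure-free class (the lowest label)."""
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in rows.columns]
        if missing:
            raise ValueError(f"rows are missing trained features: {missing}")
        x = rows.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(rows, dtype=float))
        if x.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {x.shape[1]}")
    proba = model.estimator.predict_proba(x)
    # argmax takes the first (lowest) class on ties -> seizure-free
    return model.estimator.classes_[np.argmax(proba, axis=1)]


def compute_metrics(c: ConfusionCounts) -> dict:
    """The five performance percentages from one set of confusion counts.

    SEN = TP/(TP+FN), SPEC = TN/(TN+FP), ACC = (TP+TN)/total,
    F = 2TP/(2TP+FP+FN), MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FN)(TN+FP)),
    each ×100.  An undefined SEN/SPEC (empty class) is reported as None;
    a zero MCC denominator yields MCC = 0 (degenerate).
    """
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    sen = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    total = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / total if total > 0 else None
    f = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else None
    denom = np.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = 100.0 * (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {"SEN": sen, "SPEC": spec, "ACC": acc, "F": f, "MCC": mcc}


def confusion_from_predictions(y_true, y_pred, positive=1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    return ConfusionCounts(
        tp=int(np.sum(pos & (y_pred == positive))),
        tn=int(np.sum(~pos & (y_pred != positive))),
        fp=int(np.sum(~pos & (y_pred == positive))),
        fn=int(np.sum(pos & (y_pred != positive))),
    )


def cross_validate(table, labels, n_folds: int = 10, n_repeats: int = 10,
                   n_trees: int = 100, rng_seed: int = 0,
                   fit_predict=None) -> EvaluationReport:
    """Repeated stratified k-fold evaluation.

    Confusion counts are pooled over the k folds within each repeat; the
    five metrics are computed per repeat from the pooled counts and averaged
    over repeats.

    ``fit_predict(train_x, train_y, test_x) -> predictions`` may replace the
    random forest (used to validate the fold bookkeeping against
    deterministic rule-based classifiers).
    """
    x, names = _as_matrix(table)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} records < n_folds={n_folds}; "
            f"use fewer folds")
    master = np.random.SeedSequence(rng_seed).generate_state(2 * n_repeats)
    fold_counts: list[list[ConfusionCounts]] = []
    repeat_metrics: list[dict] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(master[2 * rep] % (2 ** 31)))
        rep_counts = []
        for train_idx, test_idx in skf.split(x, y):
            if fit_predict is not None:
                pred = fit_predict(x[train_idx], y[train_idx], x[test_idx])
            else:
                model = train_forest(
                    pd.DataFrame(x[train_idx], columns=names), y[train_idx],
                    n_trees=n_trees,
                    rng_seed=int(master[2 * rep + 1] % (2 ** 31)))
                pred = predict(model, pd.DataFrame(x[test_idx], columns=names))
            rep_counts.append(confusion_from_predictions(y[test_idx], pred))
        pooled = sum(rep_counts[1:], rep_counts[0])
        fold_counts.append(rep_counts)
        repeat_metrics.append(compute_metrics(pooled))
    metrics = {}
    for name in METRIC_NAMES:
        vals = [m[name] for m in repeat_metrics if m[name] is not None]
        metrics[name] = float(np.mean(vals)) if vals else None
    return EvaluationReport(fold_counts=fold_counts, repeat_metrics=repeat_metrics,
                            metrics=metrics, n_repeats=n_repeats, n_folds=n_folds)
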