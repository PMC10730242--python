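"""Ensemble stacking classifier for endotype replication and external prediction.

Heterogeneous base learners (gradient-boosted trees, random forest, multinomial
logistic regression) are fitted per stratified fold; a multinomial logistic
meta-learner is trained strictly on the out-of-fold class probabilities, so the
stack never sees a base learner's resubstitution optimism. New cohorts must be
standardized with the training cohort's statistics before prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["StackingModel", "fit_stacking", "predict_endotypes"]


def _base_learners(seed: int) -> dict:
    return {
        "gbdt": HistGradientBoostingClassifier(random_state=seed, max_iter=150),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1),
        "logit": LogisticRegression(max_iter=2000, C=1.0),
    }


@dataclass
class StackingModel:
    base_models: dict                 # name -> fitted estimator (on all data)
    meta_model: LogisticRegression
    classes: np.ndarray
    variables: list
    folds: int
    seed: int
    oof_probabilities: np.ndarray = field(repr=False, default=None)
    oof_accuracy: float = float("nan")
    per_class_recall: dict = field(default_factory=dict)


def _check_table(table, variables=None) -> tuple[np.ndarray, list]:
    if isinstance(table, pd.DataFrame):
        cols = list(table.columns) if variables is None else variables
        missing = [v for v in cols if v not in table.columns]
        if missing:
            raise ValueError(f"schema mismatch; missing columns: {missing}")
        X = table[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        cols = variables if variables is not None else [f"x{i}" for i in range(X.shape[1])]
        if len(cols) != X.shape[1]:
            raise ValueError("schema mismatch: wrong number of columns")
    if np.isnan(X).any():
        raise ValueError("missing values are not accepted (no silent imputation)")
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    return X, cols


def fit_stacking(table, labels, folds: int = 5, seed: int = 0) -> StackingModel:
    """Fit the stacking ensemble on standardized variables and endotype labels.

    The meta-learner is trained only on out-of-fold base predictions; the base
    learners are then refitted on the full data for deployment. Reports
    out-of-fold accuracy and per-class recall.
    """
    X, cols = _check_table(table)
    y = np.asarray(getattr(labels, "labels", labels))
    if y.shape[0] != X.shape[0]:
        raise ValueError("labels must align with table rows")
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < folds]
    if too_small.size:
        raise ValueError(f"class {too_small[0]} has fewer members than folds={folds}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    names = list(_base_learners(seed))
    K = classes.size
    oof = np.zeros((X.shape[0], len(names) * K))
    for tr, te in skf.split(X, y):
        learners = _base_learners(seed)
        for j, name in enumerate(names):
            est = learners[name]
            est.fit(X[tr], y[tr])
            oof[te, j * K:(j + 1) * K] = est.predict_proba(X[te])

    meta = LogisticRegression(max_iter=2000)
    meta.fit(oof, y)
    oof_pred = meta.predict(oof)
    recall = {int(c): float(np.mean(oof_pred[y == c] == c)) for c in classes}

    full = _base_learners(seed)
    for name in names:
        full[name].fit(X, y)

    return StackingModel(base_models=full, meta_model=meta, classes=classes,
                         variables=cols, folds=folds, seed=seed,
                         oof_probabilities=oof,
                         oof_accuracy=float(np.mean(oof_pred == y)),
                         per_class_recall=recall)


def predict_endotypes(model: StackingModel, table) -> tuple[np.ndarray, np.ndarray]:
    """Predicted endotype labels and the full class-probability matrix.

    The table must carry the training variables (new cohorts standardized with
    the training statistics); rows with missing values are rejected.
    """
    X, _ = _check_table(table, model.variables)
    K = model.classes.size
    stacked = np.hstack([model.base_models[name].predict_proba(X)
                         for name in model.base_models])
    proba = model.meta_model.predict_proba(stacked)
    proba = proba / proba.sum(axis=1, keepdims=True)
    labels = model.classes[np.argmax(proba, axis=1)]
    return labels, proba


def stacking_predict_fn(model: StackingModel):
    """Probability function (n x p array -> n x K) for attribution methods."""
    def fn(X):
        X = np.asarray(X, dtype=float)
        stacked = np.hstack([model.base_models[name].predict_proba(X)
                             for name in model.base_models])
        return model.meta_model.predict_proba(stacked)
    return fn
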