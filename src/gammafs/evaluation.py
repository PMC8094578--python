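"""Classifier evaluation of nested feature subsets.

A linear maximum-margin classifier (soft-margin SVM with linear kernel,
fixed regularization, no tuning) is fitted on each nested subset and scored
with accuracy, sensitivity, specificity and the Matthews correlation
coefficient, under two resampling schemes:

* stratified 5-fold cross-validation repeated 10 times on the training data
  (mean +/- sd over the 50 fold evaluations), and
* a fixed model evaluated on B bootstrap resamples of an independent
  validation set (median and interquartile range).

Features are standardized inside every training fold (the raw HRV features
span several orders of magnitude, which would otherwise dominate the linear
kernel); the scaler is learned on the training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ValidationError

__all__ = [
    "EvalReport",
    "confusion_metrics",
    "fit_linear_margin_classifier",
    "repeated_cv_evaluate",
    "bootstrap_evaluate",
]

METRICS = ("accuracy", "sensitivity", "specificity", "mcc")

#: fixed soft-margin regularization constant (conventional solver default)
SVM_C = 1.0


@dataclass(frozen=True)
class EvalReport:
    """Performance per nested subset size under one resampling scheme.

    ``table`` is tidy: one row per (subset_size, metric) with the central
    value (mean for repeated CV, median for bootstrap validation) and its
    dispersion (sd, respectively IQR).
    """

    scheme: str                 # "repeated_cv" | "bootstrap_validation"
    table: pd.DataFrame         # subset_size, added_feature, metric, central, dispersion
    layout: dict = field(default_factory=dict)
    seed: object = None

    def metric(self, name: str) -> pd.DataFrame:
        """Rows of one metric, indexed by subset size."""
        sub = self.table[self.table["metric"] == name]
        return sub.set_index("subset_size")[["added_feature", "central", "dispersion"]]


def confusion_metrics(y_true, y_pred) -> dict:
    """Accuracy, sensitivity, specificity and MCC for 0/1 labels.

    Class 1 is the positive class (AF in the rhythm application).  MCC is 0
    by convention whenever a factor of its denominator is 0; sensitivity
    (specificity) is 0 when no positive (negative) truth is present.
    """
    yt = np.asarray(y_true).astype(int).ravel()
    yp = np.asarray(y_pred).astype(int).ravel()
    if yt.size == 0:
        raise ValidationError("empty input")
    if yt.shape != yp.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    tp = float(np.sum((yt == 1) & (yp == 1)))
    tn = float(np.sum((yt == 0) & (yp == 0)))
    fp = float(np.sum((yt == 0) & (yp == 1)))
    fn = float(np.sum((yt == 1) & (yp == 0)))
    acc = (tp + tn) / yt.size
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec, "mcc": float(mcc)}


def fit_linear_margin_classifier(train, labels):
    """Fit the linear maximum-margin classifier h(x) = theta^T x + b.

    Returns a fitted pipeline (per-fold standardization + linear-kernel SVM,
    C fixed at :data:`SVM_C`); ``.predict`` maps h(x) >= 0 to class 1.
    """
    X = train.to_numpy(dtype=float) if isinstance(train, pd.DataFrame) else np.asarray(train, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int).ravel()
    if np.unique(y).size < 2:
        raise ValidationError("training data contains a single class")
    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=SVM_C))
    clf.fit(X, y)
    return clf


def _as_df(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])


def _added_features(subsets):
    """Name of the feature each nested subset adds over the previous one."""
    added, prev = [], set()
    for s in subsets:
        new = [f for f in s if f not in prev]
        added.append(new[0] if len(new) == 1 else "+".join(new))
        prev = set(s)
    return added


def _tidy(scheme, rows, layout, seed) -> EvalReport:
    return EvalReport(scheme=scheme,
                      table=pd.DataFrame(rows,
                                         columns=["subset_size", "added_feature",
                                                  "metric", "central", "dispersion"]),
                      layout=layout, seed=seed)


def repeated_cv_evaluate(features, labels, subsets, folds: int = 5,
                         repeats: int = 10, seed=None) -> EvalReport:
    """Repeated stratified k-fold evaluation of each nested subset.

    For every subset the classifier is refitted on each training fold and
    scored on the held-out fold; the report carries the mean and sd of each
    metric over the ``folds * repeats`` evaluations.
    """
    df = _as_df(features)
    y = np.asarray(labels).astype(int).ravel()
    if y.shape[0] != len(df):
        raise ValidationError("labels length does not match feature rows")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValidationError(
            f"every class needs >= {folds} members for {folds}-fold stratification"
        )
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                       random_state=seed)
    splits = list(splitter.split(df, y))
    rows = []
    for subset, added in zip(subsets, _added_features(subsets)):
        Xs = df.loc[:, list(subset)].to_numpy(dtype=float)
        per_fold = {m: [] for m in METRICS}
        for tr, te in splits:
            clf = fit_linear_margin_classifier(Xs[tr], y[tr])
            scores = confusion_metrics(y[te], clf.predict(Xs[te]))
            for m in METRICS:
                per_fold[m].append(scores[m])
        for m in METRICS:
            vals = np.asarray(per_fold[m])
            rows.append((len(subset), added, m, float(vals.mean()),
                         float(vals.std(ddof=1))))
    return _tidy("repeated_cv", rows,
                 {"folds": folds, "repeats": repeats}, seed)


def bootstrap_evaluate(train, train_labels, validation, validation_labels,
                       subsets, B: int = 1000, seed=None) -> EvalReport:
    """Bootstrap-validation evaluation of each nested subset.

    One model per subset is fitted on the full training set; metrics are then
    computed on B bootstrap resamples of the validation set, reported as the
    median with the interquartile range as dispersion.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    df_tr, df_va = _as_df(train), _as_df(validation)
    y_tr = np.asarray(train_labels).astype(int).ravel()
    y_va = np.asarray(validation_labels).astype(int).ravel()
    if np.unique(y_va).size < 2:
        raise ValidationError("validation set must contain both classes")
    rng = np.random.default_rng(seed)
    n_va = len(df_va)
    boot_idx = rng.integers(0, n_va, size=(B, n_va))  # shared across subsets
    rows = []
    for subset, added in zip(subsets, _added_features(subsets)):
        cols = list(subset)
        clf = fit_linear_margin_classifier(df_tr.loc[:, cols], y_tr)
        pred = clf.predict(df_va.loc[:, cols].to_numpy(dtype=float))
        reps = {m: np.empty(B) for m in METRICS}
        for b in range(B):
            idx = boot_idx[b]
            scores = confusion_metrics(y_va[idx], pred[idx])
            for m in METRICS:
                reps[m][b] = scores[m]
        for m in METRICS:
            q25, q50, q75 = np.quantile(reps[m], [0.25, 0.5, 0.75])
            rows.append((len(subset), added, m, float(q50), float(q75 - q25)))
    return _tidy("bootstrap_validation", rows, {"B": B}, seed)
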