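"""Bootstrap-replicated univariate importance ranking and nested subsets.

Each feature is scored on its own (gamma separability by default, rank-based
AUC as a built-in baseline) on B stratified bootstrap resamples of the data.
Features are then ranked by the median of their B scores, descending, and the
nested candidate subsets are the prefixes of that ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import DegenerateClassError, ValidationError
from .gamma import fit_class_ellipsoid, pairwise_separation

__all__ = [
    "ImportanceRanking",
    "score_features_gamma",
    "score_features_auc",
    "SCORERS",
    "bootstrap_ranking",
    "nested_subsets",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-feature score distributions over bootstrap replicates.

    Attributes
    ----------
    scores : (B, p) ndarray
        Score of each feature on each replicate.
    medians : (p,) ndarray
        Column medians of ``scores``.
    order : list of str
        Feature names sorted by median, descending; ties broken by the
        original column order so the ranking is a total order.
    feature_names : list of str
    scorer_name : str
    B : int
    seed : int or None
    """

    scores: np.ndarray
    medians: np.ndarray
    order: list
    feature_names: list
    scorer_name: str
    B: int
    seed: object = None

    def replicate_rankings(self) -> list:
        """Descending-score ranking (total order) of every replicate."""
        p = len(self.feature_names)
        out = []
        for b in range(self.scores.shape[0]):
            idx = np.lexsort((np.arange(p), -self.scores[b]))
            out.append([self.feature_names[i] for i in idx])
        return out


def _validate_xy(features, labels, min_per_class: int = 2):
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("labels length does not match feature rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")
    if counts.min() < min_per_class:
        raise DegenerateClassError(
            f"every class needs >= {min_per_class} observations"
        )
    return X, y, names, classes


def score_features_gamma(features, labels) -> np.ndarray:
    """Univariate gamma separability of each feature.

    Entry ``j`` equals the gamma metric computed on feature ``j`` alone
    (identical code path to ``gamma_metric`` on the singleton subset).
    """
    X, y, _, classes = _validate_xy(features, labels)
    p = X.shape[1]
    scores = np.empty(p)
    for j in range(p):
        col = X[:, j:j + 1]
        ells = [fit_class_ellipsoid(col[y == k]) for k in classes]
        total = 0.0
        for a in range(len(ells)):
            for b in range(a + 1, len(ells)):
                total += pairwise_separation(ells[a], ells[b]).distance
        scores[j] = total
    return scores


def score_features_auc(features, labels) -> np.ndarray:
    """Orientation-free rank-statistic AUC of each feature as a sole score.

    Entry ``j`` is ``max(AUC_j, 1 - AUC_j)`` for the positive (greater) class,
    so a feature that separates perfectly in either direction scores 1.
    """
    X, y, _, classes = _validate_xy(features, labels)
    if classes.size != 2:
        raise ValidationError("AUC importance requires exactly 2 classes")
    y_bin = (y == classes[1]).astype(int)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        auc = roc_auc_score(y_bin, X[:, j])
        scores[j] = max(auc, 1.0 - auc)
    return scores


SCORERS = {
    "gamma": score_features_gamma,
    "auc": score_features_auc,
}


def _stratified_resample(rng, y, classes):
    idx = np.empty(0, dtype=int)
    for k in classes:
        members = np.nonzero(y == k)[0]
        idx = np.concatenate([idx, rng.choice(members, size=members.size, replace=True)])
    return idx


def bootstrap_ranking(features, labels, scorer="gamma", B: int = 150,
                      seed=None, stratify: bool = True) -> ImportanceRanking:
    """Rank features by the median of B bootstrap importance scores.

    Resampling is stratified by class by default (plain resampling can wipe
    out a rare class); with ``stratify=False`` a replicate that leaves any
    class with fewer than 2 observations is redrawn (bounded retries).
    """
    if isinstance(scorer, str):
        if scorer not in SCORERS:
            raise ValidationError(
                f"unknown scorer {scorer!r}; registered: {sorted(SCORERS)}"
            )
        scorer_name, scorer_fn = scorer, SCORERS[scorer]
    else:
        scorer_name, scorer_fn = getattr(scorer, "__name__", "custom"), scorer
    if B < 1:
        raise ValidationError("B must be >= 1")
    X, y, names, classes = _validate_xy(features, labels)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    p = len(names)
    scores = np.empty((B, p))
    for b in range(B):
        if stratify:
            idx = _stratified_resample(rng, y, classes)
        else:
            for _ in range(_MAX_REDRAWS):
                idx = rng.integers(0, n, size=n)
                _, counts = np.unique(y[idx], return_counts=True)
                if counts.size == classes.size and counts.min() >= 2:
                    break
            else:
                raise DegenerateClassError(
                    "could not draw a bootstrap replicate keeping every class"
                )
        scores[b] = scorer_fn(X[idx], y[idx])
        if not np.all(np.isfinite(scores[b])):
            raise ValidationError(f"scorer produced non-finite values on replicate {b}")
    medians = np.median(scores, axis=0)
    idx = np.lexsort((np.arange(p), -medians))
    return ImportanceRanking(
        scores=scores,
        medians=medians,
        order=[names[i] for i in idx],
        feature_names=names,
        scorer_name=scorer_name,
        B=B,
        seed=seed,
    )


def nested_subsets(ranking, max_size: int) -> list:
    """Prefixes of the ranking: subsets of size 1..max_size, each adding the
    next-ranked feature to the previous one."""
    order = ranking.order if isinstance(ranking, ImportanceRanking) else list(ranking)
    if not 1 <= max_size <= len(order):
        raise ValidationError(
            f"max_size must be in 1..{len(order)}, got {max_size}"
        )
    return [order[: k + 1] for k in range(max_size)]
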