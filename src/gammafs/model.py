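"""Model-style front end tying the pipeline stages together.

``GammaFeatureSelection`` is constructed from a labeled feature table;
``fit()`` runs the full strategy — bootstrap importance ranking, stability
profile, nested subsets, repeated-CV classifier evaluation — and returns a
``GammaFeatureSelectionResults`` carrying the estimates with their dispersion
and a ``summary()`` table.  Out-of-sample bootstrap validation of the fitted
subsets hangs off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import derive_seed
from .evaluation import EvalReport, bootstrap_evaluate, repeated_cv_evaluate
from .exceptions import ValidationError
from .selection import ImportanceRanking, bootstrap_ranking, nested_subsets
from .stability import stability_profile

__all__ = ["GammaFeatureSelection", "GammaFeatureSelectionResults"]


class GammaFeatureSelection:
    """Filter feature selection on a labeled feature table.

    Parameters
    ----------
    features : DataFrame
        n x p numeric feature table.
    labels : array_like
        Binary class labels, 0 = negative (e.g. NSR), 1 = positive (AF).
    scorer : str
        Registered importance scorer: ``"gamma"`` (default) or ``"auc"``.
    """

    def __init__(self, features: pd.DataFrame, labels, scorer: str = "gamma"):
        if not isinstance(features, pd.DataFrame):
            features = pd.DataFrame(np.asarray(features, dtype=float))
            features.columns = [f"f{j}" for j in range(features.shape[1])]
        self.features = features
        self.labels = np.asarray(labels).astype(int).ravel()
        if self.labels.shape[0] != len(features):
            raise ValidationError("labels length does not match feature rows")
        self.scorer = scorer

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       scorer: str = "gamma") -> "GammaFeatureSelection":
        if label_col not in df.columns:
            raise ValidationError(f"missing label column {label_col!r}")
        return cls(df.drop(columns=[label_col]), df[label_col], scorer=scorer)

    def fit(self, B: int = 150, seed=None, max_subset_size: int | None = None,
            cv_folds: int = 5, cv_repeats: int = 10,
            evaluate: bool = True) -> "GammaFeatureSelectionResults":
        """Run ranking, stability and (optionally) repeated-CV evaluation."""
        p = self.features.shape[1]
        max_size = p if max_subset_size is None else min(max_subset_size, p)
        ranking = bootstrap_ranking(self.features, self.labels, scorer=self.scorer,
                                    B=B, seed=derive_seed(seed, "ranking"))
        stability = stability_profile(ranking.replicate_rankings(),
                                      range(1, max_size + 1))
        subsets = nested_subsets(ranking, max_size)
        evaluation = None
        if evaluate:
            evaluation = repeated_cv_evaluate(self.features, self.labels, subsets,
                                              folds=cv_folds, repeats=cv_repeats,
                                              seed=derive_seed(seed, "cv"))
        return GammaFeatureSelectionResults(self, ranking, stability, subsets,
                                            evaluation, seed)


class GammaFeatureSelectionResults:
    """Fitted ranking, stability profile and evaluation of the nested subsets."""

    def __init__(self, model: GammaFeatureSelection, ranking: ImportanceRanking,
                 stability: dict, subsets: list, evaluation: EvalReport | None,
                 seed):
        self.model = model
        self.ranking = ranking
        self.stability = stability
        self.subsets = subsets
        self.evaluation = evaluation
        self.seed = seed

    @property
    def order(self) -> list:
        return self.ranking.order

    def validate(self, validation_features: pd.DataFrame, validation_labels,
                 B: int = 1000, seed=None) -> EvalReport:
        """Bootstrap validation of the selected subsets on held-out data."""
        return bootstrap_evaluate(self.model.features, self.model.labels,
                                  validation_features, validation_labels,
                                  self.subsets, B=B,
                                  seed=derive_seed(seed if seed is not None else self.seed,
                                                   "validation"))

    def summary(self) -> str:
        """Human-readable per-subset-size table."""
        lines = [
            "Gamma-metric filter feature selection",
            f"  scorer: {self.ranking.scorer_name}   replicates: {self.ranking.B}"
            f"   features: {len(self.ranking.feature_names)}",
            "",
            f"{'size':>4}  {'added feature':<14}{'median score':>13}{'KI':>8}"
            + ("" if self.evaluation is None else
               f"{'accuracy':>18}{'MCC':>16}"),
        ]
        med = dict(zip(self.ranking.feature_names, self.ranking.medians))
        acc = mcc = None
        if self.evaluation is not None:
            acc = self.evaluation.metric("accuracy")
            mcc = self.evaluation.metric("mcc")
        for k, subset in enumerate(self.subsets, start=1):
            feat = subset[-1]
            row = f"{k:>4}  {feat:<14}{med[feat]:>13.4f}{self.stability[k]:>8.3f}"
            if acc is not None and k in acc.index:
                row += (f"{acc.loc[k, 'central']:>10.4f} ({acc.loc[k, 'dispersion']:.4f})"
                        f"{mcc.loc[k, 'central']:>8.3f} ({mcc.loc[k, 'dispersion']:.3f})")
            lines.append(row)
        return "\n".join(lines)

    def plot_performance(self, ax=None):
        """Metric-vs-subset-size diagnostic plot (repeated-CV means)."""
        if self.evaluation is None:
            raise ValidationError("results were fitted with evaluate=False")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for metric in ("accuracy", "sensitivity", "specificity", "mcc"):
            tab = self.evaluation.metric(metric)
            ax.errorbar(tab.index, tab["central"], yerr=tab["dispersion"],
                        label=metric, capsize=2)
        ax.set_xlabel("number of selected features")
        ax.set_ylabel("metric")
        ax.legend()
        return ax
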