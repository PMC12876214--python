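"""Random-forest discrimination of cases vs controls.

Features are fungal genus abundances plus clinical covariates (total and
allergen-specific IgE).  The model is assessed by stratified k-fold
cross-validated AUC (out-of-fold scores pooled across folds, the stabler
choice at n around 36; per-fold AUCs are also emitted) and by the
out-of-bag (OOB) error of a forest refit on all samples.

Two importance measures are reported: mean-decrease-Gini (impurity based,
always >= 0) and permutation importance (which can legitimately go negative
for uninformative features — the only way a "negative importance" can arise
in a random forest).  Random forests split on feature order statistics, so
monotone transforms of a covariate (e.g. rank or log of IgE) leave the
trees unchanged; no covariate transform is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core_io import AbundanceTable, SampleMetadata


@dataclass
class ClassifierReport:
    importance: pd.DataFrame  # gini_importance, permutation_importance
    cv_auc: float
    fold_aucs: list
    n_folds: int
    oob_error: float
    n_trees: int
    seed: int | None

    def __post_init__(self) -> None:
        if (self.importance["gini_importance"] < 0).any():
            raise ValueError("Gini importance cannot be negative")
        if not (0 <= self.cv_auc <= 1):
            raise ValueError("cv_auc must be in [0, 1]")
        if not (0 <= self.oob_error <= 1):
            raise ValueError("oob_error must be in [0, 1]")


class RandomForestDiscriminator(BaseEstimator, ClassifierMixin):
    """Cross-validated random forest with dual importance reporting.

    Parameters
    ----------
    n_folds : int
        Requested stratified folds; silently reduced (with a warning) when
        the smallest class cannot populate them.
    n_trees : int
        Forest size (default 500).
    n_permutation_repeats : int
        Repeats for the permutation-importance estimate.
    seed : int or None
        Controls fold assignment, tree bootstraps and permutations.

    Fitted attributes: ``report_`` (:class:`ClassifierReport`), plus the
    underlying ``forest_``.
    """

    def __init__(self, n_folds: int = 10, n_trees: int = 500,
                 n_permutation_repeats: int = 10, seed: int | None = None):
        self.n_folds = n_folds
        self.n_trees = n_trees
        self.n_permutation_repeats = n_permutation_repeats
        self.seed = seed

    def fit(self, X, y) -> "RandomForestDiscriminator":
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index)
        classes = sorted(y.unique())
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        if len(classes) != 2:
            raise ValueError("AUC reporting assumes exactly 2 classes")
        pos = classes[0]  # alphabetical; e.g. ARFC before HC
        y01 = (y == pos).astype(int)

        min_class = int(y01.value_counts().min())
        n_folds = self.n_folds
        if n_folds > min_class:
            warnings.warn(
                f"reducing folds from {n_folds} to {min_class} "
                "(smallest class size)"
            )
            n_folds = min_class
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=self.seed)
        oof = np.zeros(len(y01))
        fold_aucs = []
        for train, test in skf.split(X.values, y01.values):
            rf = RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed
            ).fit(X.values[train], y01.values[train])
            prob = rf.predict_proba(X.values[test])[:, list(rf.classes_).index(1)]
            oof[test] = prob
            if len(np.unique(y01.values[test])) == 2:
                fold_aucs.append(float(roc_auc_score(y01.values[test], prob)))
        cv_auc = float(roc_auc_score(y01.values, oof))

        forest = RandomForestClassifier(
            n_estimators=self.n_trees, oob_score=True, random_state=self.seed
        ).fit(X.values, y01.values)
        perm = permutation_importance(
            forest, X.values, y01.values,
            n_repeats=self.n_permutation_repeats, random_state=self.seed,
        )
        importance = pd.DataFrame(
            {
                "gini_importance": forest.feature_importances_,
                "permutation_importance": perm.importances_mean,
            },
            index=X.columns,
        ).sort_values("gini_importance", ascending=False)

        self.classes_ = np.array(classes)
        self.positive_class_ = pos
        self.feature_names_ = list(X.columns)
        self.forest_ = forest
        self.report_ = ClassifierReport(
            importance=importance, cv_auc=cv_auc, fold_aucs=fold_aucs,
            n_folds=n_folds, oob_error=float(1.0 - forest.oob_score_),
            n_trees=self.n_trees, seed=self.seed,
        )
        return self

    def predict(self, X):
        y01 = self.forest_.predict(pd.DataFrame(X).values)
        neg = [c for c in self.classes_ if c != self.positive_class_][0]
        return np.where(y01 == 1, self.positive_class_, neg)

    def predict_proba(self, X):
        return self.forest_.predict_proba(pd.DataFrame(X).values)


def cv_random_forest(features, labels, n_folds: int = 10, n_trees: int = 500,
                     seed: int | None = None) -> ClassifierReport:
    """Functional wrapper around :class:`RandomForestDiscriminator`."""
    est = RandomForestDiscriminator(n_folds=n_folds, n_trees=n_trees, seed=seed)
    return est.fit(features, labels).report_


def classification_features(table: AbundanceTable,
                            metadata: SampleMetadata,
                            kingdom: str = "fungi") -> pd.DataFrame:
    """Assemble the discrimination feature matrix: one kingdom's genus
    abundances joined with total and allergen-specific IgE."""
    taxa = table.taxa_of(kingdom)
    feats = table.data[taxa].copy()
    feats["total_ige"] = metadata.frame.loc[feats.index, "total_ige"]
    for col in metadata.specific_ige_columns:
        feats[col] = metadata.frame.loc[feats.index, col]
    return feats
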