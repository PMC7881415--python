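"""Group discrimination on segmented-object features.

Four classifiers (random forest, adaptive boosting, RBF support-vector
machine, linear discriminant analysis) are trained on a stratified 70%
split of the object table and evaluated on the held-out 30%: confusion
matrices, accuracies, and impurity-based feature importances for the
tree ensembles. Feature distributions between groups are compared with
Gaussian KDEs plus a two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import stats_core

__all__ = [
    "ALGORITHM_NAMES",
    "AlgorithmResult",
    "ClassifierReport",
    "DistributionComparison",
    "train_and_evaluate",
    "rank_feature_importance",
    "compare_feature_distributions",
]

ALGORITHM_NAMES = ("random_forest", "adaboost", "svm", "lda")
TREE_ENSEMBLES = ("random_forest", "adaboost")


def _make_estimator(name: str, seed: int):
    # fixed default hyperparameters, recorded in the report
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown algorithm {name!r}")


@dataclass(frozen=True)
class AlgorithmResult:
    algorithm: str
    confusion: pd.DataFrame      # rows = true class, cols = predicted
    accuracy: float
    importances: Optional[pd.Series]  # tree ensembles only, sums to 1
    hyperparameters: dict


@dataclass(frozen=True)
class ClassifierReport:
    results: dict                # algorithm -> AlgorithmResult
    classes: tuple
    split_seed: int
    train_fraction: float
    n_train: int
    n_test: int


def train_and_evaluate(features: pd.DataFrame,
                       labels,
                       train_fraction: float = 0.7,
                       seed: int = 0,
                       algorithms: Sequence[str] = ALGORITHM_NAMES,
                       stratify: bool = True) -> ClassifierReport:
    """Fit the named classifiers on a random train/test split.

    The split is stratified by class (keeps per-class proportions within
    one object) unless ``stratify=False``. Fully deterministic per seed.

    Raises on single-class input and on non-finite features (the
    offending column is named).
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        raise ValueError("need at least 2 objects per class")
    if not np.all(np.isfinite(X)):
        bad = [c for c in features.columns
               if not np.all(np.isfinite(features[c].to_numpy(dtype=float)))]
        raise ValueError(f"non-finite feature value(s) in column(s) {bad}")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed,
        stratify=y if stratify else None)

    results = {}
    for name in algorithms:
        est = _make_estimator(name, seed)
        est.fit(X_tr, y_tr)
        pred = est.predict(X_te)
        cm = confusion_matrix(y_te, pred, labels=classes)
        cm_df = pd.DataFrame(cm, index=[f"true_{c}" for c in classes],
                             columns=[f"pred_{c}" for c in classes])
        importances = None
        if name in TREE_ENSEMBLES:
            importances = pd.Series(est.feature_importances_,
                                    index=list(features.columns), name="importance")
        results[name] = AlgorithmResult(
            algorithm=name,
            confusion=cm_df,
            accuracy=float(accuracy_score(y_te, pred)),
            importances=importances,
            hyperparameters=est.get_params(deep=False),
        )
    return ClassifierReport(results=results, classes=tuple(classes),
                            split_seed=seed, train_fraction=train_fraction,
                            n_train=len(y_tr), n_test=len(y_te))


def rank_feature_importance(report: ClassifierReport,
                            algorithm: str = "random_forest") -> pd.DataFrame:
    """Features sorted by impurity-based importance, descending; ties
    broken by feature name. Requires a tree-ensemble result."""
    if algorithm not in report.results or report.results[algorithm].importances is None:
        raise ValueError("no tree-ensemble model with importances in this report")
    imp = report.results[algorithm].importances
    df = imp.rename("importance").rename_axis("feature").reset_index()
    df = df.sort_values(["importance", "feature"],
                        ascending=[False, True]).reset_index(drop=True)
    return df


@dataclass(frozen=True)
class DistributionComparison:
    grid: Optional[np.ndarray]
    kde_a: Optional[np.ndarray]
    kde_b: Optional[np.ndarray]
    t_statistic: float
    p_value: float
    degenerate: bool = False


def compare_feature_distributions(group_a, group_b,
                                  bandwidth=None,
                                  grid_size: int = 512) -> DistributionComparison:
    """Gaussian KDEs of two feature distributions on a shared grid, plus
    a two-sided two-sample t-test on the means.

    ``bandwidth`` follows scipy's ``bw_method`` (default Silverman).
    Zero-variance pooled data degenerates the KDE to a spike and is
    flagged instead of estimated.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 values per group")
    tt = stats_core.group_compare([a, b], method="t")
    pooled = np.concatenate([a, b])
    if np.var(pooled) == 0:
        warnings.warn("zero-variance data: KDE degenerates to a spike", stacklevel=2)
        return DistributionComparison(grid=None, kde_a=None, kde_b=None,
                                      t_statistic=tt.statistic, p_value=tt.p_value,
                                      degenerate=True)
    bw = bandwidth if bandwidth is not None else "silverman"
    kde_a = gaussian_kde(a, bw_method=bw)
    kde_b = gaussian_kde(b, bw_method=bw)
    pad = 4.0 * max(kde_a.factor * a.std(), kde_b.factor * b.std())
    grid = np.linspace(pooled.min() - pad, pooled.max() + pad, grid_size)
    return DistributionComparison(grid=grid, kde_a=kde_a(grid), kde_b=kde_b(grid),
                                  t_statistic=tt.statistic, p_value=tt.p_value)
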