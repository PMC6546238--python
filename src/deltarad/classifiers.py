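"""Two-year-survival classifier benchmark.

Five classifier families fit with fixed default hyperparameters (no
tuning) on repeated stratified train/test splits; the result is the mean
test AUC per (family x image set), the usual heatmap summary. The
families are scikit-learn analogues of the glmnet / random forest / SVM /
LogitBoost / rpart lineup; exact numerical equivalence with those R
defaults is not claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort_compare import auc_mann_whitney

logger = logging.getLogger(__name__)

CLASSIFIER_FAMILIES = ("glmnet", "rf", "svm", "LogitBoost", "rpart")


def _make_classifier(family: str, seed: int):
    if family == "glmnet":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(C=1.0, max_iter=1000))
    if family == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if family == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="rbf", gamma="scale", C=1.0))
    if family == "LogitBoost":
        return GradientBoostingClassifier(random_state=seed)
    if family == "rpart":
        return DecisionTreeClassifier(min_samples_split=20, random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}")


def _score(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class ClassifierBenchmarkResult:
    mean_auc: pd.DataFrame   # families x image sets
    n_repetitions: int


def _stratified_split(rng: np.random.Generator, y: np.ndarray,
                      test_frac: float):
    """Index split keeping both classes in train and test."""
    for _ in range(100):
        test = np.zeros(len(y), dtype=bool)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            k = max(1, int(round(test_frac * len(idx))))
            test[rng.choice(idx, size=k, replace=False)] = True
        if len(np.unique(y[~test])) == 2 and len(np.unique(y[test])) == 2:
            return ~test, test
        logger.warning("degenerate split resampled")
    raise RuntimeError("could not produce a class-complete split")


def classifier_benchmark(feature_tables: dict[str, pd.DataFrame],
                         two_year: pd.Series,
                         n_repetitions: int = 47,
                         test_frac: float = 1 / 3,
                         seed: int = 0) -> ClassifierBenchmarkResult:
    """Mean test AUC per classifier family and image set.

    Patients with an undefined two-year endpoint (censored before two
    years) are excluded. Splits are stratified on the endpoint; a split
    missing a class is resampled and logged. Identical seeds give an
    identical heatmap.
    """
    labels = two_year.dropna()
    y_all = labels.astype(int)
    image_sets = list(feature_tables)
    aucs = {fam: {s: [] for s in image_sets} for fam in CLASSIFIER_FAMILIES}
    rng = np.random.default_rng(seed)
    for rep in range(n_repetitions):
        rep_seed = int(rng.integers(2 ** 31))
        for image_set in image_sets:
            table = feature_tables[image_set].dropna(axis=1)
            table = table.loc[:, table.std(ddof=0) > 0]
            idx = labels.index.intersection(table.index)
            X = table.loc[idx].to_numpy(float)
            y = y_all.loc[idx].to_numpy()
            tr, te = _stratified_split(rng, y, test_frac)
            for fam in CLASSIFIER_FAMILIES:
                model = _make_classifier(fam, rep_seed)
                model.fit(X[tr], y[tr])
                aucs[fam][image_set].append(
                    auc_mann_whitney(_score(model, X[te]), y[te]))
    mean_auc = pd.DataFrame(
        {s: [float(np.mean(aucs[fam][s])) for fam in CLASSIFIER_FAMILIES]
         for s in image_sets},
        index=list(CLASSIFIER_FAMILIES))
    return ClassifierBenchmarkResult(mean_auc, n_repetitions)
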